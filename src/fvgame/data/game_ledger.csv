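day,goal_cups,goal_g,target_food,nontarget_food,met
1,0.15,27,Mandarin Oranges,Salad,yes
2,0.15,24,Oranges,Veggie Sticks,yes
3,0.11,12,Veggie Sticks,Bananas,yes
4,0.15,39,Applesauce,Carrots,no
5,0.15,23,Bananas,Carrots,yes
6,0.11,12,Veggie Sticks,Oranges,yes
7,0.11,13,Carrots,Apples,yes
8,0.15,25,Oranges,Corn,no
9,0.15,33,Peaches,Salad,yes
10,0.15,29,Mandarin Oranges,Salad,yes
11,0.12,13,Veggie Sticks,Oranges,yes
12,0.15,39,Applesauce,Carrots,yes
13,0.12,18,Green Beans,Oranges,yes
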