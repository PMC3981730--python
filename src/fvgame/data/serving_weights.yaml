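# Grams per quarter-cup serving, by menu variety.
#
# Two weights are measured values reported for this cafeteria (salad and
# green beans). Every other entry is a SYNTHETIC fixture value: a plausible
# per-quarter-cup weight chosen from USDA-style density tables so that the
# simulator and unit conversions have a complete menu to work with. Replace
# with measured weights when analysing real records.
grams_per_quarter_cup:
  salad: 14.25            # measured
  green beans: 38.25      # measured (canned)
  veggie sticks: 30.0     # synthetic (raw carrot + celery sticks)
  carrots: 32.0           # synthetic
  corn: 41.0              # synthetic (canned)
  oranges: 45.0           # synthetic (fresh, peeled)
  mandarin oranges: 49.0  # synthetic (canned)
  bananas: 37.5           # synthetic (fresh, peeled)
  applesauce: 61.0        # synthetic (canned)
  peaches: 40.0           # synthetic (canned)
  apples: 27.5            # synthetic (fresh, cored)

category:
  salad: vegetable
  green beans: vegetable
  veggie sticks: vegetable
  carrots: vegetable
  corn: vegetable
  oranges: fruit
  mandarin oranges: fruit
  bananas: fruit
  applesauce: fruit
  peaches: fruit
  apples: fruit

# Varieties that are served with dressing; the dressing weight is subtracted
# from the consumption numerator whenever it is recorded.
dressed:
  - salad
  - veggie sticks
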