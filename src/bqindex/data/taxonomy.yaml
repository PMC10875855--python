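# Default food taxonomy: reporting groups -> scoring class + member food codes.
#
# Reporting groups are the ~25 foods/beverages observed at breakfast in an
# Italian nutrition survey; scoring classes are the aggregates used by the
# breakfast-quality indices:
#   cereals_derivatives  = bread and substitutes; breakfast cereals; other
#                          cereals; cakes/pies/biscuits
#   fruit_vegetables     = any type of fruit, nuts and vegetables
#   dairy                = milk; yoghurt; cheese; other milk products; cocoa drinks
#   mufa_fats            = olive oil, vegetable oil (MUFA-rich added fats)
#   butter_margarine     = butter, margarine (SFA/trans-rich added fats)
#   simple_sugar_sources = added sugar, jam, honey
#   other                = everything else (never contributes to a criterion)
#
# Notes on edge groups: fruit juice is reported separately from fruit and does
# not count as fruit_vegetables; nut spread is its own group (not
# fruit_vegetables); cocoa drinks (milk-based) are dairy whereas
# cocoa/energy drinks are not.  water and mixed_dishes exist so that
# non-breakfast recall rows classify cleanly; both are scoring-neutral.
groups:
  milk:
    scoring_class: dairy
    items: [milk, whole_milk, semi_skimmed_milk, skimmed_milk]
  yogurt:
    scoring_class: dairy
    items: [yogurt, yoghurt]
  cheese:
    scoring_class: dairy
    items: [cheese, ricotta]
  other_milk_products:
    scoring_class: dairy
    items: [other_milk_products, milk_dessert]
  cocoa_drinks:
    scoring_class: dairy
    items: [cocoa_drinks, milk_cocoa]
  bread_substitutes:
    scoring_class: cereals_derivatives
    items: [bread_substitutes, bread, rusks, crackers]
  breakfast_cereals:
    scoring_class: cereals_derivatives
    items: [breakfast_cereals, muesli, cornflakes]
  other_cereals:
    scoring_class: cereals_derivatives
    items: [other_cereals]
  cakes_pies_biscuits:
    scoring_class: cereals_derivatives
    items: [cakes_pies_biscuits, biscuits, cake, croissant]
  fruit:
    scoring_class: fruit_vegetables
    items: [fruit, apple, pear, banana, orange]
  nuts:
    scoring_class: fruit_vegetables
    items: [nuts, walnuts, almonds]
  vegetables:
    scoring_class: fruit_vegetables
    items: [vegetables, tomato]
  olive_oil:
    scoring_class: mufa_fats
    items: [olive_oil]
  vegetable_fat_oil:
    scoring_class: mufa_fats
    items: [vegetable_fat_oil, vegetable_oil]
  butter_margarine:
    scoring_class: butter_margarine
    items: [butter_margarine, butter, margarine]
  added_sugar:
    scoring_class: simple_sugar_sources
    items: [added_sugar, sugar]
  jam_honey:
    scoring_class: simple_sugar_sources
    items: [jam_honey, jam, honey]
  coffee:
    scoring_class: other
    items: [coffee, espresso]
  tea:
    scoring_class: other
    items: [tea]
  fruit_juice:
    scoring_class: other
    items: [fruit_juice, orange_juice]
  soft_drinks:
    scoring_class: other
    items: [soft_drinks, cola]
  cocoa_energy_drinks:
    scoring_class: other
    items: [cocoa_energy_drinks, energy_drink]
  nut_spread:
    scoring_class: other
    items: [nut_spread, hazelnut_spread]
  snacks:
    scoring_class: other
    items: [snacks, salty_snack]
  meat_fish_eggs:
    scoring_class: other
    items: [meat_fish_eggs, ham, egg]
  vegetarian_vegan:
    scoring_class: other
    items: [vegetarian_vegan, soy_drink]
  water:
    scoring_class: other
    items: [water, tap_water]
  mixed_dishes:
    scoring_class: other
    items: [mixed_dishes, mixed_meal]
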