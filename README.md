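# bqindex

Breakfast-quality scoring and correlates from single-day 24-hour dietary
recalls, for nutritional epidemiologists working with survey data.

Breakfast quality is hard to compare across studies because "a good
breakfast" mixes food choices (cereals, dairy, fruit), energy adequacy and
nutrient limits. The Breakfast Quality Index (BQI) condenses a recall day
into a 0–10 additive score — one point per criterion met — with separate
adult and child/adolescent variants. `bqindex` implements both, the
pre-scoring participant selection cascade, the descriptive tables used to
present such indices, regression models of their sociodemographic and
psychosocial correlates, and a synthetic survey-cohort generator with
planted, recoverable covariate effects for validation.

## The index

For an adult recall day with `EO` eating occasions, daily energy `E` (kcal)
and breakfast intakes (subscript *b*), one point each for:

| component | criterion |
|---|---|
| cereals, fruit/vegetables, dairy | group present at breakfast (3 points; intake, not amount) |
| combination | all three groups in the same breakfast meal |
| energy share | 0.15 ≤ E_b / E ≤ 0.25 |
| free sugar | 4·sugar_b < 0.10·E / EO |
| calcium | Ca_b ≥ 0.20·RDA(life stage) |
| saturated fat | 9·SFA_b < 0.10·E / EO |
| fibre | fibre_b > 25 g / EO |
| sodium | Na_b < 2000 mg / EO |

No points are removed for unhealthy foods. Categories: low 0–3,
medium 4–6, high 7–10.

The child/adolescent variant scores presence of cereals, dairy,
fruit/vegetables and MUFA-rich added fats (olive/vegetable oil); energy from
simple-sugar sources < 5% of daily energy; breakfast MUFA:SFA strictly above
the cohort median (a population-relative criterion, so cohorts are scored in
two passes); energy share within 20–25%; breakfast calcium within
200–300 mg; absence of butter/margarine; and the cereals–fruit–dairy
combination. Categories: low 0–4, medium 5, high 6–10.

## Worked example

```python
import bqindex as b

tax = b.load_taxonomy()          # packaged food-group mapping
rda = b.load_rda_table()         # packaged calcium reference intakes

milk = b.FoodIntake("milk", 200, b.NutrientProfile(energy_kcal=92, calcium_mg=240,
                                                   sfa_g=2.2, mufa_g=1.0, sodium_mg=90))
biscuits = b.FoodIntake("biscuits", 30, b.NutrientProfile(energy_kcal=190, free_sugar_g=8,
                                                          sodium_mg=120))
apple = b.FoodIntake("apple", 150, b.NutrientProfile(energy_kcal=78, fibre_g=2.0, sodium_mg=30))
breakfast = b.EatingOccasion("breakfast", [milk, biscuits, apple], time="07:30")
lunch = b.EatingOccasion("lunch", [b.FoodIntake("mixed_meal", 400, b.NutrientProfile(energy_kcal=620))])
snack = b.EatingOccasion("snack", [b.FoodIntake("mixed_meal", 150, b.NutrientProfile(energy_kcal=220))])
dinner = b.EatingOccasion("dinner", [b.FoodIntake("mixed_meal", 450, b.NutrientProfile(energy_kcal=800))])
day = b.DietaryDay("A0001", [breakfast, lunch, snack, dinner])

result = b.score_adult(day, tax, rda, sex="woman", age_years=45)
print("components:", {k: int(v) for k, v in result.components.items()})
print("score:", result.score, "| category:", result.category)
```

prints

```
components: {'cereals': 1, 'fruit_veg': 1, 'dairy': 1, 'combination': 1,
             'energy_share': 1, 'free_sugar': 1, 'calcium': 1, 'sfa': 1,
             'fibre': 0, 'sodium': 1}
score: 9 | category: high
```

Reading the output: the day has 4 eating occasions and 1910 kcal, so the
breakfast of 360 kcal sits at an 18.8% energy share (in the 15–25% window);
every nutrient limit is met except fibre (2 g at breakfast versus the
25/4 = 6.25 g threshold), leaving 9 of 10 points and a "high" category.

## Command line

```bash
bqi simulate --stream adult --n 2000 --seed 42 --out data/
bqi score-adult --recall data/recall.csv --participants data/participants.csv --out scores.csv
bqi describe --scores scores.csv --recall data/recall.csv --participants data/participants.csv --out tables/
bqi correlates --scores scores.csv --recall data/recall.csv --participants data/participants.csv --out tables/
# or everything from one config:
bqi pipeline --config demo.yaml
```

On a 2,000-adult synthetic cohort (seed 42) the pipeline reports a mean
score of 4.38 (SD 1.41) with category shares low/medium/high =
28.5/64.9/6.7%, and milk (37.4%), tea (14.9%), coffee (13.4%), bread (8.6%)
and cakes/biscuits (8.6%) as the top gram contributors to breakfast — the
same qualitative surface the index was designed to describe in Italian
survey data. Output tables carry a `#`-comment metadata header (version,
config hash, seed); read them back with `pandas.read_csv(..., comment="#")`.

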