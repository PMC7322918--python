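"""Exposure-derivation rules: smoking, alcohol, HPV16 E6 serostatus.

Builds a handful of questionnaire records and prints how each rule
classifies them.
"""

from epimediate import (QuestionnaireRecord, cigarette_equivalents_per_day,
                        classify_hpv_serostatus, derive_alcohol_units,
                        derive_smoking_status)

records = {
    "never answered yes": QuestionnaireRecord(),
    "100 lifetime cigarettes": QuestionnaireRecord(lifetime_cigarettes=100),
    "a cigar every fourth day, 2 years": QuestionnaireRecord(
        cigars_per_day=0.25, years_smoked=2),
    "half a cigarette daily, 10 years": QuestionnaireRecord(
        cigarettes_per_day=0.5, years_smoked=10),
}
print("Ever/never smoking (>=1 product-equivalent/day for >=1 year, or "
      ">=100 lifetime cigarettes; one cigar = four cigarettes):")
for label, q in records.items():
    status = "ever" if derive_smoking_status(q) else "never"
    print(f"  {label:36s} {cigarette_equivalents_per_day(q):4.1f} eq/day"
          f" -> {status}")

q = QuestionnaireRecord(wine_units=10, spirit_units=5, beer_units=7.5)
print(f"\nWeekly alcohol units (10 wine + 5 spirit + 7.5 beer): "
      f"{derive_alcohol_units(q):.1f} units/week")

print("\nHPV16 E6 serostatus (MFI >= 1000 is seropositive):")
for mfi in (0.0, 999.99, 1000.0, 2500.0):
    print(f"  MFI {mfi:8.2f} -> "
          f"{'positive' if classify_hpv_serostatus(mfi) else 'negative'}")
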