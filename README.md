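# banffdx

Rule-based Banff rejection classification for kidney-allograft biopsies,
with pathologist-vs-engine concordance analysis and a synthetic cohort
generator.

## The problem

The Banff classification assigns renal-allograft biopsies to rejection
categories from ordinal lesion scores (tubulitis *t*, interstitial
inflammation *i*, intimal arteritis *v*, glomerulitis *g*, peritubular
capillaritis *ptc*, C4d staining, and the chronic lesions *cg*, *cv*,
*ci*, *ct*, *ptcbm*, plus the IFTA-region scores *t-IFTA* and *i-IFTA*).
The schema has grown intricate enough that non-pathologists running
retrospective studies struggle to apply it consistently across eras.
`banffdx` implements a deterministic rule engine mapping one score vector
plus minimal clinical context — donor-specific antibody (DSA) status and
ABO compatibility — to a primary diagnostic category, and the analysis
machinery to compare such automated calls against pathologist diagnoses.

The engine is calibrated against, and regression-tested on, 49 published
row-level discrepancy cases (27 antibody-mediated rejection, 22
T-cell-mediated rejection) from a 1,071-biopsy cohort rich in
ABO-incompatible transplants.

## The rules

**Antibody-mediated rejection (AMR).** Requires both:

1. *Histologic microvascular injury*: g ≥ 1, or isolated peritubular
   capillaritis (ptc ≥ 1 with g = 0) unless the capillaritis is better
   explained by concurrent full TCMR (exempted when C4d evidence and
   MVI = g + ptc ≥ 2 both hold) or occurs in an ABO-incompatible graft
   without positive DSA.
2. *Antibody–endothelium interaction*: C4d ≥ 2 in an ABO-**compatible**
   graft, or MVI ≥ 2. C4d positivity in ABO-incompatible grafts is
   expected without rejection and never counts.

Chronicity (transplant glomerulopathy cg ≥ 1) upgrades to chronic active
AMR; unknown DSA without C4d evidence yields "equivocal for AMR".

**T-cell-mediated rejection (TCMR).** Acute grades: v = 1/2/3 → IIA/IIB/III;
i ≥ 2 with t = 2/3 → IA/IB. Borderline change (BC): v = 0, no grade, and
(t ≥ 1 with i ≤ 1, or i ≥ 2 with t = 1). Chronic active TCMR: i-IFTA ≥ 2
with t ≥ 2, or with t-IFTA ≥ 2 and ct ≥ 2.

**Assembly.** IFTA is graded I–III from max(ci, ct); isolated C4d
positivity in a compatible graft with no other finding is "C4d staining
without evidence of rejection". The primary category is the
highest-priority applicable one:

    A-AMR (incl. equivocal) > CA-AMR > A-TCMR > CA-TCMR >
    chronic AMR inactive > BC > IFTA > C4d-no-rejection > no rejection

## Worked example

```python
from banffdx import (
    Abo, BanffLesionScores, BiopsyRecord, ClinicalContext, Dsa, classify_biopsy,
)

record = BiopsyRecord(
    record_id="bx1", patient_id="p1",
    scores=BanffLesionScores(t=0, i=0, v=0, g=1, ptc=1, c4d=2,
                             cg=0, cv=0, ci=0, ct=0, ptcbm=0),
    context=ClinicalContext(dsa=Dsa.NEGATIVE, abo=Abo.INCOMPATIBLE),
)
result = classify_biopsy(record)
print(result.primary.value)
print(sorted(c.value for c in result.applicable))
print(result.trace[:4])
```

prints

```
A-AMR
['A-AMR']
('amr.mvi=2', 'amr.c4d_evidence=no', 'amr.criterion1=yes', 'amr.criterion2=yes')
```

— glomerulitis plus capillaritis reach the MVI ≥ 2 interaction threshold,
so active AMR is diagnosed even though the ABO-incompatible C4d stain is
discounted and DSA is negative.

From the shell, the same engine runs over cohort CSVs:

```
banffdx fixtures table1 -o table1.csv
banffdx classify table1.csv -o calls.csv
banffdx concordance table1.csv
banffdx simulate --n 1000 --seed 7 -o synthetic.csv
```

`concordance` prints an agreement report (stratified rates plus a
Cohen's-kappa extension) and can export the pathologist × engine flow
table as long CSV or Sankey-ready JSON.

## Limitations

The engine classifies from scores and two clinical flags only. It cannot
see prior biopsies, treatment response, or non-rejection diseases, which
is precisely where automated and pathologist diagnoses part ways; see
`docs/methods.md` for the calibration details and known deviations.
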