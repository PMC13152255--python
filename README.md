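# sgecurate

Clinical interpretation of *BRCA2* variants that combines ACMG/AMP
point-based classification with functional evidence from two independent
saturation-genome-editing (SGE) screens of the C-terminal DNA-binding
domain — one in haploid human HAP1 cells, one in mouse embryonic stem
(mES) cells.  It is written for clinical-genetics curators and
methodologists who want the arithmetic of variant reassessment —
evidence points, PS3/BS3 integration, Bayesian posteriors, agreement
statistics — as a tested, scriptable library rather than a spreadsheet.

## What it computes

**Point-based classification.** Each applied evidence code converts to a
signed integer by its strength (supporting/moderate/strong/very strong =
±1/±2/±4/±8; suffixes like `PM2_P` override the family default), and the
total maps onto five tiers:

    PV >= 10,  LPV 6..9,  VUS -1..5,  LBV -6..-2,  BV <= -7

**SGE integration.** Each screen bins a variant into seven categories
(points +4…−4).  When the two screens agree in sign, the variant gains
PS3 (pathogenic) or BS3 (benign) at the stronger of the two levels and
is reclassified; when they disagree, no functional evidence is assigned.

**Multifactorial likelihood.** With prior probability *P* and combined
likelihood ratio LR (a product of history/pathology/co-occurrence
components), the posterior odds are the prior odds times LR:

    posterior = P·LR / (P·LR + 1 − P)

mapped onto IARC classes 1–5 (class 5 > 0.99 … class 1 ≤ 0.001), with no
class assigned while LR lies in the uninformative window [0.5, 2].

**Agreement statistics.** A functional call opposite to a definitive
classification is a *major error*; an uncertain call for a definitive
classification, or a definitive call for a VUS, a *minor error*.  The
two screens' per-variant agreement categories are compared with the
Bhapkar chi-square test of marginal homogeneity (the k-category
generalization of McNemar's test).

A synthetic-cohort generator (`sgecurate.simulate`) produces cohorts
with known true classes, consistent evidence sets, paired SGE categories
with configurable discordance/corruption rates, and lognormal LR
components, so every stage can be exercised against ground truth.

## Worked example

Two fixture tables ship with the package: 13 variants on which the
screens disagree, and 29 VUS on which they agree.  Reclassifying the
latter:

```python
from sgecurate import apply_integration
from sgecurate.datasets import load_concordant_vus

for rec in load_concordant_vus()[:3]:
    out = apply_integration(list(rec.evidence), rec.sge_hap1, rec.sge_mes)
    print(rec.variant_id, out.evidence.assigned_code.label,
          out.pre.label, "->", out.post.label, f"({out.post.total_points} pts)")
```

prints

```
c.7805G>A PS3 VUS -> LPV (7 pts)
c.8069T>A PS3 VUS -> LPV (6 pts)
c.9221T>C PS3 VUS -> LPV (8 pts)
```

i.e. each variant's concordant pathogenic SGE pair contributes PS3 (+4),
lifting the point total out of the uncertain band.  Over all 29 VUS, 27
(93.1%) reclassify — 3 to likely pathogenic, 24 to likely benign.  On
the 13 discordant variants, `examples/concordance_rates.py` reports
major/minor/concordance rates of 15.4/46.2/38.5% (HAP1) and
23.1/38.5/38.5% (mES), not significantly different by the Bhapkar test.
The `examples/` directory holds one short script per capability; the
`sgecurate` command exposes the same stages as subcommands (`classify`,
`integrate-sge`, `multifactorial`, `concordance`, `simulate`, `report`).

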