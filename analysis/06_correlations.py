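#!/usr/bin/env python
"""Genetic, maternal and phenotypic correlations among the traits.

Fits the three bivariate trait-mean models (BW2-BW7, BW2-RATIO,
BW7-RATIO) and the extended trait x reaction-norm models, and applies the
significance conventions (one-tailed 0.98 SE for variances, two-tailed
1.96 SE for correlations).

What to expect: strong positive BW2-BW7 genetic correlation, near-zero
BW2-RATIO correlations (early growth independent of resistance), a
negative BW7-RATIO correlation created by the tolerance slope, and a
weak/nonsignificant RATIO-slope genetic correlation (no resistance-
tolerance trade-off in the generator).
"""

from pathlib import Path

import pandas as pd

from tolgen import data_io, models
from tolgen.pedigree import load_pedigree
from tolgen.report import correlation_significant

ROOT = Path(__file__).resolve().parents[1]


def main():
    pop = ROOT / "results" / "population"
    ped = load_pedigree(pop / "pedigree.csv")
    tab = data_io.load_phenotypes(pop / "phenotypes.csv", ped)
    out = ROOT / "results" / "correlations"
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    for t1, t2 in (("bw2", "bw7"), ("bw2", "ratio"), ("bw7", "ratio")):
        rep = models.bivariate_fit(tab, ped, t1, t2)
        for term, kind in (("animal", "genetic"), ("dam", "maternal")):
            est, se = models.correlation_from_bivariate(
                rep, term, f"{t1}.mean", f"{t2}.mean"
            )
            sig = correlation_significant(max(min(est, 1), -1), se if se == se else 0.0)
            rows.append({"pair": f"{t1}-{t2}", "kind": kind, "estimate": est,
                         "se": se, "significant": sig.significant})
            print(f"{t1}-{t2} {kind}: {est:+.2f} +- {se:.2f}"
                  f"{' *' if sig.significant else ''}")
        est, se = models.phenotypic_correlation(rep, t1, t2)
        rows.append({"pair": f"{t1}-{t2}", "kind": "phenotypic", "estimate": est,
                     "se": se, "significant": None})
        print(f"{t1}-{t2} phenotypic: {est:+.2f} +- {se:.2f}")

    # trait x (intercept, slope) blocks via the extended joint fits
    for trait in ("bw2", "ratio"):
        rep = models.extended_fit(tab, ped, trait)
        for other in ("bw7.intercept", "bw7.slope"):
            est, se = models.correlation_from_bivariate(
                rep, "animal", f"{trait}.mean", other
            )
            rows.append({"pair": f"{trait}-{other}", "kind": "genetic",
                         "estimate": est, "se": se, "significant": None})
            print(f"{trait}-{other} genetic: {est:+.2f} +- {se:.2f}")

    pd.DataFrame(rows).to_csv(out / "correlations.csv", index=False)
    print(f"wrote {out}/correlations.csv")


if __name__ == "__main__":
    main()
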