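"""Genomic heritabilities and genetic correlations across cohorts.

Univariate GREML per cohort (array GRM), then the trivariate model treating
home-cow, overseas-cow and heifer RFI as correlated traits.  Writes the
variance-component table under results/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from rfigp import genio
from rfigp.grm import build_grm_yang
from rfigp.mixedmodel import fit_greml, genetic_correlation, heritability
from rfigp.pipeline import DataBundle, Scenario, assemble_traits, prepare_phenotypes

DATA = Path(__file__).resolve().parents[1] / "results" / "data"
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    gm = genio.read_plink(DATA / "array")
    records = genio.read_phenotypes(DATA / "records.tsv")
    ped = genio.read_phenotypes(DATA / "pedigree.tsv")
    seq = genio.read_plink(DATA / "sequence")
    seq.variants = pd.read_csv(DATA / "variants.tsv", sep="\t",
                               dtype={"chrom": str, "id": str})
    bundle = DataBundle(seq, ped, records)
    phenos = prepare_phenotypes(bundle)
    grm = build_grm_yang(gm, "auto")

    rows = []
    scn = Scenario("tri", tuple(phenos["dataset"].unique()), "trivariate", "array")
    traits = assemble_traits(phenos, scn)
    for td in traits:
        vc_u = fit_greml(td, grm)
        h2, se = heritability(vc_u)
        rows.append({"model": "univariate", "trait": td.name, "n": td.y.size,
                     "Vg": vc_u.P[0, 0], "Ve": vc_u.R[0, 0],
                     "h2": h2, "se_h2": se})

    vc = fit_greml(traits, grm)
    for t, td in enumerate(traits):
        h2, se = heritability(vc, t)
        rows.append({"model": "trivariate", "trait": td.name, "n": td.y.size,
                     "Vg": vc.P[t, t], "Ve": vc.R[t, t], "h2": h2, "se_h2": se})
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "variance_components.tsv", sep="\t", index=False)

    rg_rows = []
    names = [td.name for td in traits]
    for a in range(len(traits)):
        for b in range(a + 1, len(traits)):
            rg, se = genetic_correlation(vc, a, b)
            rg_rows.append({"pair": f"{names[a]}-{names[b]}", "rg": rg, "se": se})
    pd.DataFrame(rg_rows).to_csv(OUT / "genetic_correlations.tsv", sep="\t",
                                 index=False)

    print(table.round(3).to_string(index=False))
    print(pd.DataFrame(rg_rows).round(3).to_string(index=False))
    print(f"trivariate GREML converged={vc.converged} after {vc.n_iterations} "
          f"iterations, logL={vc.log_likelihood:.2f}")


if __name__ == "__main__":
    main()
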