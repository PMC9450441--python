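"""Generate the default multi-country synthetic bundle.

Writes PLINK triplets (sequence + array densities), lactation records,
pedigree and the hidden simulation truth under results/data/.  All later
analysis steps read from there, so the whole analysis is reproducible from
one seed.
"""

from pathlib import Path

from rfigp import genio
from rfigp.synthetic_data import SimulationConfig, make_panel, simulate_bundle

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
SEED = 2024


def main() -> None:
    cfg = SimulationConfig(seed=SEED)
    gm, ped, records, truth = simulate_bundle(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    genio.write_plink(gm, OUT / "sequence")
    genio.write_plink(make_panel(gm, "array"), OUT / "array")
    gm.variants.to_csv(OUT / "variants.tsv", sep="\t", index=False)
    genio.write_phenotypes(records, OUT / "records.tsv")
    genio.write_phenotypes(ped, OUT / "pedigree.tsv")
    genio.write_phenotypes(truth, OUT / "truth.tsv")
    n_cows = (ped["dataset"] != "home_heifer").sum()
    print(f"bundle: {gm.n_animals} animals ({n_cows} cows), "
          f"{gm.n_variants} sequence variants, "
          f"{int(gm.variants['panel_array'].sum())} array variants, "
          f"{int(gm.variants['qtl'].sum())} causal -> {OUT}")


if __name__ == "__main__":
    main()
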