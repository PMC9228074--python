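"""Convert allocated land into potential global species loss.

Applies ecoregion characterization factors per taxon and land-use
category, then reports the accounts of the study: headline totals for
plants and the vertebrate aggregate, the within-KBA subset,
production- vs consumption-based country rankings, and per-capita
values.
"""

import argparse

import pandas as pd

from ecofoot.pipeline import PipelineConfig, stage_loss

VERTS = ("mammals", "amphibians", "reptiles", "birds")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--workdir", default="results/analysis_run")
    args = parser.parse_args()

    config = PipelineConfig(workdir=args.workdir, seed=args.seed)
    report = stage_loss(config)
    print(
        f"total potential loss: {report['total_species_loss']:.4e} "
        "species-equivalents"
    )
    print(
        f"within KBAs: {report['inside_kba_species_loss']:.4e} "
        f"({report['kba_share_pct']:.1f}% of the total)"
    )

    sl = pd.read_csv(config.workdir / "species_loss.csv")
    sl["group"] = sl["taxon"].map(
        lambda g: "vertebrates" if g in VERTS else g
    )
    headline = sl.groupby(["group", "kba"])["species_loss"].sum().unstack()
    print("\nheadline groups (species-equivalents):")
    print(headline.to_string(float_format="{:.4e}".format))

    pvc = pd.read_csv(config.workdir / "production_consumption.csv")
    plants = pvc[pvc["taxon"] == "plants"].set_index("region")
    print("\nplants, by country (production vs consumption based):")
    print(
        plants[["production_based", "consumption_based"]]
        .sort_values("consumption_based", ascending=False)
        .to_string(float_format="{:.4e}".format)
    )

    per_capita = pd.read_csv(config.workdir / "per_capita.csv")
    top = (
        per_capita[per_capita["taxon"] == "plants"]
        .nlargest(3, "consumption_based")[["region", "consumption_based"]]
    )
    print("\nlargest per-capita plant loss (species per person):")
    print(top.to_string(index=False, float_format="{:.3e}".format))


if __name__ == "__main__":
    main()
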