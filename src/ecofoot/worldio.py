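"""On-disk representation of a synthetic world.

Everything is plain text: long-format CSVs with declared index columns
for the economic tables and extensions, ESRI ASCII grids for rasters,
YAML for configuration and JSON for the ground-truth ledger.  Zero
entries of the sparse tables are omitted and restored on load, so a
save/load round trip is exact.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .biodiversity import CFTable
from .mrio import LandExtension, LinkTable, MonetaryIOTable, PhysicalIOTable
from .rasters import GridGeometry, read_ascii_grid, write_ascii_grid
from .spatial import CellMasks, LandUseGrid
from .synthetic import SyntheticWorld, WorldConfig

__all__ = ["save_world", "load_world"]


def _long_matrix(
    matrix: np.ndarray, row_index: pd.MultiIndex, col_index: pd.MultiIndex, cols
) -> pd.DataFrame:
    rows, colps = np.nonzero(matrix)
    records = {
        cols[0]: [row_index[i][0] for i in rows],
        cols[1]: [row_index[i][1] for i in rows],
        cols[2]: [col_index[j][0] for j in colps],
        cols[3]: [col_index[j][1] for j in colps],
        "value": matrix[rows, colps],
    }
    return pd.DataFrame(records)


def _read_long_matrix(
    path: Path, row_index: pd.MultiIndex, col_index: pd.MultiIndex, cols
) -> np.ndarray:
    out = np.zeros((len(row_index), len(col_index)))
    if not path.exists():
        return out
    df = pd.read_csv(path, keep_default_na=False, float_precision="round_trip")
    rpos = {key: i for i, key in enumerate(row_index)}
    cpos = {key: j for j, key in enumerate(col_index)}
    for rec in df.itertuples(index=False):
        out[rpos[(getattr(rec, cols[0]), getattr(rec, cols[1]))],
            cpos[(getattr(rec, cols[2]), getattr(rec, cols[3]))]] = rec.value
    return out


def save_world(world: SyntheticWorld, path) -> None:
    """Write a world to a directory of text files."""
    path = Path(path)
    (path / "economy").mkdir(parents=True, exist_ok=True)
    (path / "rasters" / "landuse").mkdir(parents=True, exist_ok=True)

    with open(path / "world.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "config": asdict(world.config),
                "phys_regions": world.phys.regions,
                "phys_products": world.phys.products,
                "mon_regions": world.mon.regions,
                "mon_products": world.mon.products,
                "categories": world.extension.categories,
                "units": world.phys.units,
                "cell_area_m2": world.masks.geometry.cell_area_m2,
            },
            fh,
            sort_keys=True,
        )

    phys_idx = world.phys.sectors
    mon_idx = world.mon.sectors
    econ = path / "economy"
    _long_matrix(
        world.phys.Z, phys_idx, phys_idx,
        ("origin_region", "origin_product", "dest_region", "dest_product"),
    ).to_csv(econ / "z_phys.csv", index=False)
    _long_matrix(
        world.mon.Z, mon_idx, mon_idx,
        ("origin_region", "origin_product", "dest_region", "dest_product"),
    ).to_csv(econ / "z_mon.csv", index=False)
    _long_matrix(
        world.link.Z, phys_idx, mon_idx,
        ("origin_region", "origin_product", "dest_region", "dest_product"),
    ).to_csv(econ / "z_link.csv", index=False)

    pd.DataFrame(
        {
            "region": [t[0] for t in phys_idx],
            "product": [t[1] for t in phys_idx],
            "output": world.phys.x,
            "unit": [world.phys.units.get(t[1], "") for t in phys_idx],
        }
    ).to_csv(econ / "x_phys.csv", index=False)
    pd.DataFrame(
        {
            "region": [t[0] for t in mon_idx],
            "product": [t[1] for t in mon_idx],
            "output": world.mon.x,
        }
    ).to_csv(econ / "x_mon.csv", index=False)

    def save_demand(y, row_index, consumers, name):
        rows, cols = np.nonzero(y)
        pd.DataFrame(
            {
                "origin_region": [row_index[i][0] for i in rows],
                "product": [row_index[i][1] for i in rows],
                "consumer": [consumers[j] for j in cols],
                "value": y[rows, cols],
            }
        ).to_csv(econ / name, index=False)

    save_demand(world.phys.y, phys_idx, world.phys.regions, "y_phys.csv")
    save_demand(world.mon.y, mon_idx, world.mon.regions, "y_mon.csv")

    ext = world.extension
    ir, ip, im = np.nonzero(ext.d)
    pd.DataFrame(
        {
            "region": [ext.regions[i] for i in ir],
            "product": [ext.products[i] for i in ip],
            "category": [ext.categories[i] for i in im],
            "land_m2": ext.d[ir, ip, im],
            "intensity_m2_per_unit": ext.e[ir, ip, im],
        }
    ).to_csv(path / "extension.csv", index=False)

    world.population.rename("population").rename_axis("region").reset_index().to_csv(
        path / "population.csv", index=False
    )
    pd.DataFrame(
        sorted(world.concordance.items()), columns=["phys_region", "mon_region"]
    ).to_csv(path / "concordance.csv", index=False)

    cfs = world.cfs
    g, m, e = np.meshgrid(
        np.arange(len(cfs.taxa)),
        np.arange(len(cfs.categories)),
        np.arange(len(cfs.ecoregions)),
        indexing="ij",
    )
    pd.DataFrame(
        {
            "taxon": [cfs.taxa[i] for i in g.ravel()],
            "category": [cfs.categories[i] for i in m.ravel()],
            "ecoregion": [cfs.ecoregions[i] for i in e.ravel()],
            "cf_per_m2": cfs.cf.ravel(),
        }
    ).to_csv(path / "cf.csv", index=False)
    gg, ee = np.meshgrid(
        np.arange(len(cfs.taxa)), np.arange(len(cfs.ecoregions)), indexing="ij"
    )
    pd.DataFrame(
        {
            "taxon": [cfs.taxa[i] for i in gg.ravel()],
            "ecoregion": [cfs.ecoregions[i] for i in ee.ravel()],
            "species_per_m2": cfs.richness_per_m2.ravel(),
        }
    ).to_csv(path / "richness.csv", index=False)
    cfs.taxon_totals.rename("global_species").rename_axis(
        "taxon"
    ).reset_index().to_csv(path / "taxon_totals.csv", index=False)

    rast = path / "rasters"
    geometry = world.masks.geometry
    write_ascii_grid(rast / "country_id.asc", world.masks.country_id, geometry)
    write_ascii_grid(rast / "ecoregion_id.asc", world.masks.ecoregion_id, geometry)
    write_ascii_grid(rast / "kba.asc", world.masks.kba, geometry)
    manifest = []
    for n, key in enumerate(sorted(world.land_grid.layers, key=str)):
        region, product, category = key
        fname = f"layer_{n:04d}.asc"
        write_ascii_grid(
            rast / "landuse" / fname, world.land_grid.layers[key], geometry
        )
        manifest.append(
            {
                "file": fname,
                "region": region,
                "product": "" if product is None else product,
                "category": category,
            }
        )
    pd.DataFrame(manifest).to_csv(rast / "layers.csv", index=False)

    with open(path / "ground_truth.json", "w") as fh:
        json.dump(world.ground_truth, fh, indent=2, sort_keys=True)


def load_world(path) -> SyntheticWorld:
    """Read a world previously written by :func:`save_world`."""
    path = Path(path)
    with open(path / "world.yaml") as fh:
        meta = yaml.safe_load(fh)
    cfg_dict = dict(meta["config"])
    if cfg_dict.get("population_range") is not None:
        cfg_dict["population_range"] = tuple(cfg_dict["population_range"])
    if isinstance(cfg_dict.get("kba_fraction"), list):
        cfg_dict["kba_fraction"] = tuple(cfg_dict["kba_fraction"])
    for key in ("cf_ranges", "richness_ranges"):
        if cfg_dict.get(key):
            cfg_dict[key] = {k: tuple(v) for k, v in cfg_dict[key].items()}
    config = WorldConfig(**cfg_dict)
    phys_regions = meta["phys_regions"]
    phys_products = meta["phys_products"]
    mon_regions = meta["mon_regions"]
    mon_products = meta["mon_products"]
    categories = meta["categories"]
    cell_area = float(meta["cell_area_m2"])

    phys_idx = pd.MultiIndex.from_product([phys_regions, phys_products])
    mon_idx = pd.MultiIndex.from_product([mon_regions, mon_products])
    econ = path / "economy"
    cols = ("origin_region", "origin_product", "dest_region", "dest_product")
    Z_phys = _read_long_matrix(econ / "z_phys.csv", phys_idx, phys_idx, cols)
    Z_mon = _read_long_matrix(econ / "z_mon.csv", mon_idx, mon_idx, cols)
    Z_link = _read_long_matrix(econ / "z_link.csv", phys_idx, mon_idx, cols)
    x_phys = pd.read_csv(econ / "x_phys.csv", float_precision="round_trip")["output"].to_numpy()
    x_mon = pd.read_csv(econ / "x_mon.csv", float_precision="round_trip")["output"].to_numpy()

    def load_demand(name, row_index, consumers):
        out = np.zeros((len(row_index), len(consumers)))
        df = pd.read_csv(econ / name, keep_default_na=False, float_precision="round_trip")
        rpos = {key: i for i, key in enumerate(row_index)}
        cpos = {c: j for j, c in enumerate(consumers)}
        for rec in df.itertuples(index=False):
            out[rpos[(rec.origin_region, rec.product)], cpos[rec.consumer]] = (
                rec.value
            )
        return out

    y_phys = load_demand("y_phys.csv", phys_idx, phys_regions)
    y_mon = load_demand("y_mon.csv", mon_idx, mon_regions)

    phys = PhysicalIOTable(
        regions=phys_regions,
        products=phys_products,
        Z=Z_phys,
        x=x_phys,
        y=y_phys,
        units=dict(meta["units"]),
    )
    mon = MonetaryIOTable(
        regions=mon_regions, products=mon_products, Z=Z_mon, x=x_mon, y=y_mon
    )
    link = LinkTable(Z=Z_link)

    d = np.zeros((len(phys_regions), len(phys_products), len(categories)))
    e = np.zeros_like(d)
    ext_df = pd.read_csv(path / "extension.csv", keep_default_na=False, float_precision="round_trip")
    rpos = {r: i for i, r in enumerate(phys_regions)}
    ppos = {p: i for i, p in enumerate(phys_products)}
    mpos = {m: i for i, m in enumerate(categories)}
    for rec in ext_df.itertuples(index=False):
        d[rpos[rec.region], ppos[rec.product], mpos[rec.category]] = rec.land_m2
        e[rpos[rec.region], ppos[rec.product], mpos[rec.category]] = (
            rec.intensity_m2_per_unit
        )
    extension = LandExtension(
        regions=phys_regions, products=phys_products, categories=categories, d=d, e=e
    )

    population = pd.read_csv(path / "population.csv", float_precision="round_trip").set_index("region")[
        "population"
    ]
    concordance = dict(
        pd.read_csv(path / "concordance.csv").itertuples(index=False, name=None)
    )

    cf_df = pd.read_csv(path / "cf.csv", keep_default_na=False, float_precision="round_trip")
    taxa = sorted(cf_df["taxon"].unique(), key=list(cf_df["taxon"]).index)
    ecoregions = sorted(cf_df["ecoregion"].unique())
    cf = np.zeros((len(taxa), len(categories), len(ecoregions)))
    gpos = {g: i for i, g in enumerate(taxa)}
    epos = {int(e_): i for i, e_ in enumerate(ecoregions)}
    for rec in cf_df.itertuples(index=False):
        cf[gpos[rec.taxon], mpos[rec.category], epos[int(rec.ecoregion)]] = (
            rec.cf_per_m2
        )
    rho = np.zeros((len(taxa), len(ecoregions)))
    for rec in pd.read_csv(path / "richness.csv", float_precision="round_trip").itertuples(index=False):
        rho[gpos[rec.taxon], epos[int(rec.ecoregion)]] = rec.species_per_m2
    taxon_totals = pd.read_csv(path / "taxon_totals.csv", float_precision="round_trip").set_index("taxon")[
        "global_species"
    ]
    cfs = CFTable(
        taxa=list(taxa),
        categories=list(categories),
        ecoregions=[int(e_) for e_ in ecoregions],
        cf=cf,
        richness_per_m2=rho,
        taxon_totals=taxon_totals,
    )

    rast = path / "rasters"
    country, geometry = read_ascii_grid(rast / "country_id.asc", cell_area)
    eco, _ = read_ascii_grid(rast / "ecoregion_id.asc", cell_area)
    kba, _ = read_ascii_grid(rast / "kba.asc", cell_area)
    masks = CellMasks(
        country_id=country.astype(np.int64),
        ecoregion_id=eco.astype(np.int64),
        kba=kba.astype(bool),
        geometry=geometry,
        regions=phys_regions,
    )
    layers = {}
    manifest = pd.read_csv(rast / "layers.csv", keep_default_na=False)
    for rec in manifest.itertuples(index=False):
        data, _ = read_ascii_grid(rast / "landuse" / rec.file, cell_area)
        product = rec.product if rec.product != "" else None
        layers[(rec.region, product, rec.category)] = data
    land_grid = LandUseGrid(layers=layers, geometry=geometry)

    with open(path / "ground_truth.json") as fh:
        ground_truth = json.load(fh)

    return SyntheticWorld(
        config=config,
        phys=phys,
        mon=mon,
        link=link,
        extension=extension,
        land_grid=land_grid,
        masks=masks,
        cfs=cfs,
        population=population,
        concordance=concordance,
        ground_truth=ground_truth,
    )
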