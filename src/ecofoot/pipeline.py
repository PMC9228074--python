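"""End-to-end stage orchestration with plain-file handoff.

Stages (generate → footprint → allocate → loss → flows → attribute →
ctv) exchange data only through files under the configured working
directory, so each stage is independently testable and resumable.  A
stage writes its outputs plus a manifest recording SHA-256 hashes of
the files it read and wrote; reruns with identical inputs are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import biodiversity, spatial, synthetic, worldio
from .ctv import FACTORS, ctv as compute_ctv, decompose
from .errors import ConfigError, PipelineDependencyError
from .mrio import FootprintTensor, consumption_footprint
from .synthetic import WorldConfig

__all__ = [
    "PipelineConfig",
    "STAGES",
    "WorldAnalysis",
    "analyze_world",
    "run",
    "stage_generate",
    "stage_footprint",
    "stage_allocate",
    "stage_loss",
    "stage_flows",
    "stage_attribute",
    "stage_ctv",
]

logger = logging.getLogger("ecofoot")

STAGES = ("generate", "footprint", "allocate", "loss", "flows", "attribute", "ctv")


@dataclass
class PipelineConfig:
    """Run-wide settings; loadable from YAML.

    ``region_groups`` maps regions onto flow-matrix groups (defaults to
    one group per region); product groupings default to identity.
    """

    workdir: Path = Path("results/run")
    seed: int = 0
    world: dict = field(default_factory=dict)
    stages: tuple = STAGES
    conservation_rel_tol: float = 1e-9
    strict_cf: bool = True
    region_groups: dict | None = None
    food_product_groups: dict | None = None
    nonfood_product_groups: dict | None = None
    attribution_kba: str = "total"

    def __post_init__(self):
        self.workdir = Path(self.workdir)
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ConfigError(f"unknown stages: {unknown}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def world_config(self) -> WorldConfig:
        params = dict(self.world)
        params.setdefault("seed", self.seed)
        for key in ("cf_ranges", "richness_ranges"):
            if params.get(key):
                params[key] = {k: tuple(v) for k, v in params[key].items()}
        if params.get("population_range") is not None:
            params["population_range"] = tuple(params["population_range"])
        if isinstance(params.get("kba_fraction"), list):
            params["kba_fraction"] = tuple(params["kba_fraction"])
        return WorldConfig(**params)

    @property
    def world_dir(self) -> Path:
        return self.workdir / "world"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _hash_tree(root: Path) -> dict[str, str]:
    return {
        str(p.relative_to(root.parent)): _sha256(p)
        for p in sorted(root.rglob("*"))
        if p.is_file()
    }


def _write_manifest(config: PipelineConfig, stage: str, inputs, outputs) -> None:
    manifest = {
        "stage": stage,
        "inputs": {
            str(Path(p).relative_to(config.workdir)): _sha256(Path(p))
            for p in sorted(map(str, inputs))
        },
        "outputs": {
            str(Path(p).relative_to(config.workdir)): _sha256(Path(p))
            for p in sorted(map(str, outputs))
        },
    }
    with open(config.workdir / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _require(config: PipelineConfig, stage: str, *paths: Path) -> None:
    missing = [str(p) for p in paths if not Path(p).exists()]
    if missing:
        raise PipelineDependencyError(
            f"stage '{stage}' needs outputs of an earlier stage; missing: {missing}"
        )


def _world_files(config: PipelineConfig) -> list[Path]:
    return [p for p in sorted(config.world_dir.rglob("*")) if p.is_file()]


# ---------------------------------------------------------------------------
# In-memory analysis (the file-based stages below wrap the same calls)


@dataclass
class WorldAnalysis:
    """All derived results of one world, computed in memory."""

    world: object
    economy: object
    footprint: FootprintTensor
    shares: spatial.SpatialShares
    grid: spatial.AllocatedLandGrid
    production_grid: spatial.AllocatedLandGrid
    account: biodiversity.SpeciesLossAccount
    flows: biodiversity.FlowMatrix
    attribution: pd.DataFrame
    decomposition: object
    ctv: object | None


def analyze_world(
    world,
    *,
    strict_cf: bool = True,
    region_groups: dict | None = None,
    food_groups: dict | None = None,
    nonfood_groups: dict | None = None,
    attribution_kba: str = "total",
    with_ctv: bool = True,
) -> WorldAnalysis:
    """Run the full accounting chain on a world without touching disk.

    Convenience wrapper used by the analysis drivers and tests; the
    file-based stages compute exactly the same quantities.
    """
    economy = world.economy()
    footprint = consumption_footprint(
        economy, world.extension, world.phys.y, world.mon.y
    )
    shares = spatial.normalize_distribution(world.land_grid, world.extension)
    grid = spatial.allocate(footprint, shares, world.masks)
    production_grid = spatial.allocate_production(
        world.extension, shares, world.masks
    )
    account = biodiversity.species_loss(
        grid, world.cfs, world.masks, strict=strict_cf
    )
    grouping = region_groups or {r: r for r in world.phys.regions}
    flows = biodiversity.trade_flows(account, grouping)
    lossfac = biodiversity.loss_factors(
        shares, world.cfs, world.masks, strict=strict_cf
    )
    attribution = biodiversity.product_attribution(
        economy,
        world.extension,
        world.phys.y,
        world.mon.y,
        lossfac,
        kba=attribution_kba,
        food_groups=food_groups,
        nonfood_groups=nonfood_groups,
    )
    decomposition = decompose(account, world.masks, world.cfs, production_grid)
    ctv_result = compute_ctv(decomposition) if with_ctv else None
    return WorldAnalysis(
        world=world,
        economy=economy,
        footprint=footprint,
        shares=shares,
        grid=grid,
        production_grid=production_grid,
        account=account,
        flows=flows,
        attribution=attribution,
        decomposition=decomposition,
        ctv=ctv_result,
    )


# ---------------------------------------------------------------------------
# Stages


def stage_generate(config: PipelineConfig) -> dict:
    """Generate the synthetic world and write it plus a balance report."""
    config.workdir.mkdir(parents=True, exist_ok=True)
    world = synthetic.generate(config.world_config())
    worldio.save_world(world, config.world_dir)
    report = synthetic.balance_check(world)
    report_path = config.workdir / "balance_report.json"
    with open(report_path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
    logger.info("generate: balance ok=%s", report.ok)
    _write_manifest(config, "generate", [], _world_files(config) + [report_path])
    return {"balance_ok": report.ok}


def _load_world(config: PipelineConfig, stage: str):
    _require(config, stage, config.world_dir / "world.yaml")
    return worldio.load_world(config.world_dir)


def _footprint_path(config: PipelineConfig) -> Path:
    return config.workdir / "footprint.csv"


def stage_footprint(config: PipelineConfig) -> dict:
    """Compute the consumption-based land-use footprint tensor."""
    world = _load_world(config, "footprint")
    economy = world.economy()
    fp = consumption_footprint(economy, world.extension, world.phys.y, world.mon.y)
    residual = fp.conservation_residual(world.extension)
    df = fp.F.to_series().rename("land_m2").reset_index()
    df = df[df["land_m2"] != 0.0]
    out_path = _footprint_path(config)
    df.to_csv(out_path, index=False)
    report = {
        "max_rel_conservation_residual": residual,
        "passed": bool(residual <= config.conservation_rel_tol),
        "total_land_m2": float(fp.total.sum()),
    }
    report_path = config.workdir / "footprint_conservation.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    logger.info("footprint: conservation residual %.3e", residual)
    _write_manifest(
        config, "footprint", _world_files(config), [out_path, report_path]
    )
    return report


def load_footprint(config: PipelineConfig, world) -> FootprintTensor:
    """Rehydrate the footprint tensor from the stage's CSV."""
    import xarray as xr

    df = pd.read_csv(_footprint_path(config), keep_default_na=False, float_precision="round_trip")
    shape = (
        2,
        len(world.phys.regions),
        len(world.phys.regions),
        len(world.phys.products),
        len(world.extension.categories),
    )
    data = np.zeros(shape)
    prov = {"food": 0, "nonfood": 1}
    rpos = {r: i for i, r in enumerate(world.phys.regions)}
    ppos = {p: i for i, p in enumerate(world.phys.products)}
    mpos = {m: i for i, m in enumerate(world.extension.categories)}
    data[
        df["provenance"].map(prov),
        df["consumer"].map(rpos),
        df["producer"].map(rpos),
        df["product"].map(ppos),
        df["category"].map(mpos),
    ] = df["land_m2"]
    F = xr.DataArray(
        data,
        dims=("provenance", "consumer", "producer", "product", "category"),
        coords={
            "provenance": ["food", "nonfood"],
            "consumer": world.phys.regions,
            "producer": world.phys.regions,
            "product": world.phys.products,
            "category": world.extension.categories,
        },
        name="land_footprint_m2",
    )
    return FootprintTensor(F=F)


def _grid_paths(config: PipelineConfig) -> tuple[Path, Path]:
    return config.workdir / "allocated_land.csv", config.workdir / "production_land.csv"


def stage_allocate(config: PipelineConfig) -> dict:
    """Allocate footprints to grid cells; write sparse cell tables."""
    world = _load_world(config, "allocate")
    _require(config, "allocate", _footprint_path(config))
    fp = load_footprint(config, world)
    shares = spatial.normalize_distribution(world.land_grid, world.extension)
    grid = spatial.allocate(fp, shares, world.masks)
    production = spatial.allocate_production(world.extension, shares, world.masks)

    marginals = spatial.country_marginals(grid, world.masks)
    target = fp.total.sum("product")
    scale = np.maximum(np.abs(marginals.values), np.abs(target.values))
    diff = np.abs(marginals.values - target.values)
    with np.errstate(invalid="ignore", divide="ignore"):
        residual = float(np.max(np.where(scale > 0, diff / scale, 0.0)))

    alloc_path, prod_path = _grid_paths(config)

    def save_grid(g, path):
        s, m, r, c = np.nonzero(g.data)
        pd.DataFrame(
            {
                "consumer": [g.consumers[i] for i in s],
                "category": [g.categories[i] for i in m],
                "row": r,
                "col": c,
                "land_m2": g.data[s, m, r, c],
            }
        ).to_csv(path, index=False)

    save_grid(grid, alloc_path)
    save_grid(production, prod_path)
    report = {
        "max_rel_marginal_residual": residual,
        "passed": bool(residual <= config.conservation_rel_tol),
    }
    report_path = config.workdir / "allocation_conservation.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    logger.info("allocate: marginal residual %.3e", residual)
    _write_manifest(
        config,
        "allocate",
        _world_files(config) + [_footprint_path(config)],
        [alloc_path, prod_path, report_path],
    )
    return report


def load_allocated(config: PipelineConfig, world, path, consumers):
    df = pd.read_csv(path, keep_default_na=False, float_precision="round_trip")
    categories = world.extension.categories
    data = np.zeros(
        (len(consumers), len(categories)) + world.masks.geometry.shape
    )
    spos = {s: i for i, s in enumerate(consumers)}
    mpos = {m: i for i, m in enumerate(categories)}
    data[
        df["consumer"].map(spos),
        df["category"].map(mpos),
        df["row"],
        df["col"],
    ] = df["land_m2"]
    return spatial.AllocatedLandGrid(
        data=data,
        consumers=list(consumers),
        categories=list(categories),
        geometry=world.masks.geometry,
    )


def _account_path(config: PipelineConfig) -> Path:
    return config.workdir / "species_loss.csv"


def stage_loss(config: PipelineConfig) -> dict:
    """Species loss per taxon/consumer/producer/category/KBA flag, plus
    the reported aggregation tables."""
    world = _load_world(config, "loss")
    alloc_path, _ = _grid_paths(config)
    _require(config, "loss", alloc_path)
    grid = load_allocated(config, world, alloc_path, world.phys.regions)
    account = biodiversity.species_loss(
        grid, world.cfs, world.masks, strict=config.strict_cf
    )
    df = account.sl.to_series().rename("species_loss").reset_index()
    df = df[df["species_loss"] != 0.0]
    out_path = _account_path(config)
    df.to_csv(out_path, index=False)

    pvc = biodiversity.production_vs_consumption(account)
    pvc.to_csv(config.workdir / "production_consumption.csv", index=False)
    biodiversity.per_capita(pvc, world.population).to_csv(
        config.workdir / "per_capita.csv", index=False
    )
    by_cat = (
        account.sl.sum(["consumer", "producer", "kba"])
        .to_series()
        .rename("species_loss")
        .reset_index()
    )
    by_cat.to_csv(config.workdir / "loss_by_category.csv", index=False)
    kba_split = account.by_kba().to_series().rename("species_loss").reset_index()
    kba_split.to_csv(config.workdir / "loss_by_kba.csv", index=False)

    total = account.total()
    inside = float(account.sl.sel(kba="inside").sum())
    report = {
        "total_species_loss": total,
        "inside_kba_species_loss": inside,
        "kba_share_pct": 100.0 * inside / total if total > 0 else 0.0,
    }
    logger.info("loss: total %.4e species-equivalents", total)
    outputs = [
        out_path,
        config.workdir / "production_consumption.csv",
        config.workdir / "per_capita.csv",
        config.workdir / "loss_by_category.csv",
        config.workdir / "loss_by_kba.csv",
    ]
    _write_manifest(
        config, "loss", _world_files(config) + [alloc_path], outputs
    )
    return report


def load_account(config: PipelineConfig, world) -> biodiversity.SpeciesLossAccount:
    import xarray as xr

    df = pd.read_csv(_account_path(config), keep_default_na=False, float_precision="round_trip")
    taxa = world.cfs.taxa
    regions = world.phys.regions
    categories = world.extension.categories
    flags = list(biodiversity.KBA_FLAGS)
    data = np.zeros(
        (len(taxa), len(regions), len(regions), len(categories), len(flags))
    )
    gpos = {g: i for i, g in enumerate(taxa)}
    rpos = {r: i for i, r in enumerate(regions)}
    mpos = {m: i for i, m in enumerate(categories)}
    kpos = {k: i for i, k in enumerate(flags)}
    data[
        df["taxon"].map(gpos),
        df["consumer"].map(rpos),
        df["producer"].map(rpos),
        df["category"].map(mpos),
        df["kba"].map(kpos),
    ] = df["species_loss"]
    sl = xr.DataArray(
        data,
        dims=("taxon", "consumer", "producer", "category", "kba"),
        coords={
            "taxon": taxa,
            "consumer": regions,
            "producer": regions,
            "category": categories,
            "kba": flags,
        },
        name="species_loss",
    )
    return biodiversity.SpeciesLossAccount(sl=sl)


def stage_flows(config: PipelineConfig) -> dict:
    """Embodied-loss flow matrix between region groups."""
    world = _load_world(config, "flows")
    _require(config, "flows", _account_path(config))
    account = load_account(config, world)
    grouping = config.region_groups or {r: r for r in world.phys.regions}
    flows = biodiversity.trade_flows(account, grouping)
    flows.flows.to_series().rename("species_loss").reset_index().to_csv(
        config.workdir / "flow_matrix.csv", index=False
    )
    flows.trade_share_pct.rename_axis("taxon").reset_index().to_csv(
        config.workdir / "trade_shares.csv", index=False
    )
    report = {
        "trade_share_pct": {
            g: float(v) for g, v in flows.trade_share_pct.items()
        }
    }
    _write_manifest(
        config,
        "flows",
        _world_files(config) + [_account_path(config)],
        [config.workdir / "flow_matrix.csv", config.workdir / "trade_shares.csv"],
    )
    return report


def stage_attribute(config: PipelineConfig) -> dict:
    """Attribute species loss to final products (food vs nonfood)."""
    world = _load_world(config, "attribute")
    economy = world.economy()
    shares = spatial.normalize_distribution(world.land_grid, world.extension)
    lossfac = biodiversity.loss_factors(
        shares, world.cfs, world.masks, strict=config.strict_cf
    )
    attribution = biodiversity.product_attribution(
        economy,
        world.extension,
        world.phys.y,
        world.mon.y,
        lossfac,
        kba=config.attribution_kba,
        food_groups=config.food_product_groups,
        nonfood_groups=config.nonfood_product_groups,
    )
    out_path = config.workdir / "product_attribution.csv"
    attribution.to_csv(out_path, index=False)
    by_prov = attribution.groupby("provenance")["species_loss"].sum()
    total = float(by_prov.sum())
    report = {
        "food_share_pct": 100.0 * float(by_prov.get("food", 0.0)) / total
        if total > 0
        else 0.0,
        "total_species_loss": total,
    }
    _write_manifest(config, "attribute", _world_files(config), [out_path])
    return report


def stage_ctv(config: PipelineConfig) -> dict:
    """Four-factor decomposition of within-KBA loss and its CTV table."""
    world = _load_world(config, "ctv")
    _, prod_path = _grid_paths(config)
    _require(config, "ctv", _account_path(config), prod_path)
    account = load_account(config, world)
    production = load_allocated(config, world, prod_path, ["__production__"])
    decomposition = decompose(account, world.masks, world.cfs, production)
    decomposition.table.to_csv(config.workdir / "decomposition.csv", index=False)
    result = compute_ctv(decomposition)
    result.table.to_csv(config.workdir / "ctv.csv", index=False)
    wide = result.table.pivot(index="factor", columns="taxon", values="ctv_pct")
    wide.loc[list(FACTORS)].to_csv(config.workdir / "ctv_table.csv")
    report = {
        "reconstruction_residual": decomposition.reconstruction_residual(),
        "excluded_regions": decomposition.excluded_regions(),
    }
    _write_manifest(
        config,
        "ctv",
        _world_files(config) + [_account_path(config), prod_path],
        [
            config.workdir / "decomposition.csv",
            config.workdir / "ctv.csv",
            config.workdir / "ctv_table.csv",
        ],
    )
    return report


_STAGE_FUNCS = {
    "generate": stage_generate,
    "footprint": stage_footprint,
    "allocate": stage_allocate,
    "loss": stage_loss,
    "flows": stage_flows,
    "attribute": stage_attribute,
    "ctv": stage_ctv,
}


def run(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns the run report.

    The report aggregates each stage's summary and an overall
    ``conservation_ok`` flag; a stage failure propagates with that
    stage's diagnostic.
    """
    config.workdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        logger.info("running stage %s", stage)
        report["stages"][stage] = _STAGE_FUNCS[stage](config)
    checks = []
    for name in ("footprint", "allocate"):
        if name in report["stages"] and "passed" in report["stages"][name]:
            checks.append(report["stages"][name]["passed"])
    if "generate" in report["stages"]:
        checks.append(report["stages"]["generate"]["balance_ok"])
    report["conservation_ok"] = bool(all(checks)) if checks else True
    with open(config.workdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
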