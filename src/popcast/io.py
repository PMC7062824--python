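"""Readers/writers for the published data-record formats, configuration,
and end-to-end pipeline orchestration.

Provincial population files are named ``Pop_E_<province>_SSPx_<year>.csv``
with one row per age label (0, 1, ..., 99, 100+) and one column per
sex × education combination (M/F × E0..E6, e.g. ``M_E3``).  Totals are
summarized in ``Pop_TOTAL.csv`` (province, year, scenario, total).
Population grids are written as single-band float64 GeoTIFFs (WGS84,
configurable pixel size, origin top-left, nodata −1 on water).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import downscale as ds
from . import scenarios as sc
from . import urbanization as urb
from .engine import project
from .state import (
    AGE_LABELS,
    EDU_CODES,
    N_AGE,
    N_EDU,
    N_SEX,
    SEX_CODES,
    PopulationState,
)
from .synthetic import SyntheticWorld, SyntheticWorldConfig, make_world

logger = logging.getLogger(__name__)

_COLUMNS = [f"{s}_{e}" for s in SEX_CODES for e in EDU_CODES]


def write_population_csv(
    state: PopulationState, scenario: str, outdir: Path
) -> list[Path]:
    """Write one ``Pop_E_<province>_<scenario>_<year>.csv`` per province."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, prov in enumerate(state.provinces):
        data = {
            f"{SEX_CODES[s]}_{EDU_CODES[e]}": state.counts[i, s, :, e]
            for s in range(N_SEX)
            for e in range(N_EDU)
        }
        df = pd.DataFrame(data, index=pd.Index(AGE_LABELS, name="age"))
        path = outdir / f"Pop_E_{prov}_{scenario}_{state.year}.csv"
        df.to_csv(path, float_format="%.6f")
        paths.append(path)
    return paths


def read_population_csv(
    paths: list[Path], year: int, provinces: list[str]
) -> PopulationState:
    """Reassemble a :class:`PopulationState` from per-province CSV files."""
    counts = np.zeros((len(provinces), N_SEX, N_AGE, N_EDU))
    for i, path in enumerate(paths):
        df = pd.read_csv(path, index_col="age", dtype={"age": str})
        if list(df.index) != list(AGE_LABELS):
            raise ValueError(f"{path}: age column must be 0..99, 100+")
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        for s in range(N_SEX):
            for e in range(N_EDU):
                counts[i, s, :, e] = df[f"{SEX_CODES[s]}_{EDU_CODES[e]}"].to_numpy()
    return PopulationState(counts, year, tuple(provinces))


def write_pop_total(
    states: list[PopulationState], scenario: str, path: Path
) -> pd.DataFrame:
    """Summarize totals per province/year/scenario into ``Pop_TOTAL.csv``."""
    rows = []
    for st in states:
        for i, prov in enumerate(st.provinces):
            rows.append({
                "province": prov,
                "year": st.year,
                "scenario": scenario,
                "total": float(st.counts[i].sum()),
            })
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False, float_format="%.6f")
    return df


# --- GeoTIFF ----------------------------------------------------------------

WGS84_WKT = (
    'GEOGCS["WGS 84",DATUM["WGS_1984",SPHEROID["WGS 84",6378137,'
    '298.257223563]],PRIMEM["Greenwich",0],UNIT["degree",0.0174532925199433]]'
)
NODATA = -1.0


def write_geotiff(
    path: Path,
    values: np.ndarray,
    water_mask: np.ndarray | None = None,
    pixel_size: float = 1.0 / 120.0,  # toy 30 arc-seconds
    origin: tuple[float, float] = (70.0, 54.0),  # lon, lat of top-left
) -> None:
    """Write a single-band float64 GeoTIFF with WGS84 georeferencing tags.

    Water pixels are written as the nodata value −1.
    """
    data = np.asarray(values, dtype=np.float64).copy()
    if water_mask is not None:
        data[water_mask.astype(bool)] = NODATA
    # GeoTIFF georeferencing: ModelPixelScale (33550), ModelTiepoint (33922),
    # GeoKeyDirectory (34735) declaring a geographic WGS84 CRS, GDAL nodata.
    geokeys = (1, 1, 0, 3, 1024, 0, 1, 2, 1025, 0, 1, 2, 2048, 0, 1, 4326)
    extratags = [
        (33550, "d", 3, (pixel_size, pixel_size, 0.0)),
        (33922, "d", 6, (0.0, 0.0, 0.0, origin[0], origin[1], 0.0)),
        (34735, "H", len(geokeys), geokeys),
        (42112, "s", 0, "<GDALMetadata></GDALMetadata>"),
        (42113, "s", 0, str(NODATA)),
    ]
    tifffile.imwrite(path, data, extratags=extratags)


def read_geotiff(path: Path) -> np.ndarray:
    """Read a single-band GeoTIFF written by :func:`write_geotiff`."""
    return tifffile.imread(path).astype(np.float64)


# --- configuration and pipeline --------------------------------------------


@dataclass
class RunConfig:
    """End-to-end pipeline configuration."""

    ssp_id: str = "SSP2"
    rcp_id: str = "RCP6"
    start_year: int = 2010
    end_year: int = 2100
    seed: int = 0
    n_provinces: int = 5
    raster_shape: tuple[int, int] = (120, 120)
    coarse_factor: int = 12
    outdir: Path = Path("popcast_output")
    write_yearly_csv: bool = False
    write_grids: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        ds.check_scenario_pair(self.ssp_id, self.rcp_id)
        if self.start_year < 2010 or self.end_year > 2100:
            raise ValueError("years must lie within 2010-2100")
        self.outdir = Path(self.outdir)

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "raster_shape" in raw:
            raw["raster_shape"] = tuple(raw["raster_shape"])
        return cls(**raw)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run synthetic world → scenario → projection → urbanization →
    downscaling → validation, writing artifacts and a checksum manifest.

    Returns the manifest dict (also written to ``manifest.json``).
    """
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "synthetic_census"
    try:
        world = make_world(SyntheticWorldConfig(
            n_provinces=config.n_provinces,
            raster_shape=config.raster_shape,
            coarse_factor=config.coarse_factor,
            seed=config.seed,
        ))

        stage = "scenario_builder"
        spec = sc.assemble_ssp(config.ssp_id, world)
        spec.validate()

        stage = "cohort_engine"
        states, logs = project(
            world.base_state, spec, world.base_rates, end_year=config.end_year
        )
        states = [s for s in states if config.start_year <= s.year <= config.end_year]

        stage = "urbanization"
        pu_paths, fits = [], []
        for i, prov in enumerate(world.provinces):
            assumption = urb.resolve_assumption(
                config.ssp_id, world.income_categories[i]
            )
            path, fit = urb.project_urbanization(
                prov, assumption, world.urbanization_history,
                start=config.start_year, end=config.end_year,
            )
            pu_paths.append(path)
            fits.append(fit)
        totals = {s.year: s.totals_by_province() for s in states}
        urban, rural = urb.split_urban_rural(totals, pu_paths)

        stage = "downscale"
        base_grid = ds.build_base_grid(
            world.raster.pop_raw, world.raster.water,
            world.raster.road_distance, world.raster.gravity,
        )
        grids = ds.downscale_series(
            base_grid, world.raster.province_id, urban, rural,
            world.raster.urban_fraction, config.coarse_factor,
            config.ssp_id, config.rcp_id, water_mask=world.raster.water,
        )

        stage = "validate"
        checks = []
        for year, grid in grids.items():
            sums = np.bincount(
                world.raster.province_id.ravel(), weights=grid.ravel(),
                minlength=config.n_provinces,
            )
            checks.append(float(np.abs(sums - totals[year]).max()))
        consistency = max(checks)

        stage = "output"
        artifacts: list[Path] = []
        scen = config.ssp_id
        artifacts += write_population_csv(states[0], scen, outdir)
        artifacts += write_population_csv(states[-1], scen, outdir)
        if config.write_yearly_csv:
            for st in states[1:-1]:
                artifacts += write_population_csv(st, scen, outdir)
        total_path = outdir / "Pop_TOTAL.csv"
        write_pop_total(states, scen, total_path)
        artifacts.append(total_path)

        pu_rows = [
            {"province": prov, "year": y, "assumption": fits[i].source, "PU": v}
            for i, prov in enumerate(world.provinces)
            for y, v in pu_paths[i].items()
        ]
        pu_path = outdir / "urbanization.csv"
        pd.DataFrame(pu_rows).to_csv(pu_path, index=False)
        artifacts.append(pu_path)
        fit_path = outdir / "urbanization_fits.json"
        fit_path.write_text(json.dumps([
            {
                "province": prov, "b": fits[i].b, "c": fits[i].c, "d": fits[i].d,
                "r_squared": fits[i].r_squared, "n": fits[i].n_obs,
                "source": fits[i].source,
                "reference_provinces": list(fits[i].reference_provinces),
            }
            for i, prov in enumerate(world.provinces)
        ], indent=2))
        artifacts.append(fit_path)

        scen_label = f"{config.ssp_id}_{config.rcp_id}"
        grid_years = (
            sorted(grids) if config.write_grids
            else [config.start_year, config.end_year]
        )
        for year in grid_years:
            gpath = outdir / f"{scen_label}_{year}.tif"
            write_geotiff(gpath, grids[year], water_mask=world.raster.water)
            artifacts.append(gpath)
    except Exception as err:
        raise type(err)(f"[stage: {stage}] {err}") from err

    manifest = {
        "config": {
            "ssp": config.ssp_id, "rcp": config.rcp_id, "seed": config.seed,
            "years": [config.start_year, config.end_year],
            "n_provinces": config.n_provinces,
            "raster_shape": list(config.raster_shape),
            "coarse_factor": config.coarse_factor,
        },
        "consistency_max_abs_error_persons": consistency,
        "n_grid_years": len(grids),
        "calibration_log": [
            {"year": lg.year, "fertility_scale": lg.fertility_scale,
             "migration_factor": lg.migration_factor}
            for lg in logs
        ],
        "artifacts": {str(p.name): _checksum(p) for p in artifacts},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
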