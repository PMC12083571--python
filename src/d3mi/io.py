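"""CSV input/output, run configuration and logging for federations.

Per-site tables are plain CSV (RFC-4180); missing cells are an empty field
or the literal token ``NA`` on read, and an empty field on write.  Binary
columns must contain only {0, 1, missing}.  All filesystem access for the
package funnels through this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .families import Family
from .federation import Federation, SiteData
from .mi import CompletedDataset, make_specs, mice_run
from .model import GLMMModel
from .pooling import impute_analyze_pool

logger = logging.getLogger("d3mi.io")

MISSING_TOKENS = ("", "NA")


@dataclass(frozen=True)
class SiteTableSchema:
    """Declared column roles for per-site tables."""

    outcome: str
    covariates: tuple[str, ...]
    site_column: str = "site"
    binary_columns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "covariates", tuple(self.covariates))
        object.__setattr__(self, "binary_columns", tuple(self.binary_columns))
        if self.outcome in self.covariates:
            raise ValueError("outcome cannot be a covariate")

    @property
    def data_columns(self) -> tuple[str, ...]:
        return (self.outcome,) + self.covariates


def _read_one(path: Path, schema: SiteTableSchema, need_site: bool) -> pd.DataFrame:
    df = pd.read_csv(
        path, na_values=list(MISSING_TOKENS), keep_default_na=False, dtype=str
    )
    cols = list(schema.data_columns) + ([schema.site_column] if need_site else [])
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for c in schema.data_columns:
        try:
            df[c] = pd.to_numeric(df[c])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: column {c!r}: {exc}") from exc
    for c in schema.binary_columns:
        vals = df[c].dropna()
        bad = vals[~vals.isin([0, 1])]
        if len(bad):
            line = bad.index[0] + 2  # header + 1-based
            raise ValueError(
                f"{path}, line {line}: binary column {c!r} contains {bad.iloc[0]!r}"
            )
    return df


def read_federation(
    paths: list[str | Path] | str | Path, schema: SiteTableSchema
) -> Federation:
    """Read per-site CSVs (one file per site, named by stem) or a single
    pooled CSV with a site-identifier column."""
    sites: list[SiteData] = []
    if isinstance(paths, (str, Path)):
        df = _read_one(Path(paths), schema, need_site=True)
        for site_id, grp in df.groupby(schema.site_column, sort=False):
            sites.append(_to_site(str(site_id), grp, schema))
    else:
        for p in paths:
            p = Path(p)
            df = _read_one(p, schema, need_site=False)
            sites.append(_to_site(p.stem, df, schema))
    ids = [s.site_id for s in sites]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate site ids: {sorted(ids)}")
    return Federation(sites, binary_columns=set(schema.binary_columns))


def _to_site(site_id: str, df: pd.DataFrame, schema: SiteTableSchema) -> SiteData:
    values, mask = {}, {}
    for c in schema.data_columns:
        col = df[c].to_numpy(dtype=float)
        values[c] = col
        mask[c] = np.isnan(col)
    return SiteData(site_id=site_id, values=values, mask=mask)


def write_federation(
    federation: Federation, out_dir: str | Path, write_mask: bool = True
) -> None:
    """One CSV per site; masked cells written as empty fields, plus an
    optional companion ``<site>.mask.csv`` of 0/1 flags."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in federation.sites:
        df = s.to_frame()
        masked = pd.DataFrame({c: s.mask[c].astype(int) for c in s.values})
        df = df.mask(masked.astype(bool))
        df.to_csv(out / f"{s.site_id}.csv", index=False, na_rep="")
        if write_mask:
            masked.to_csv(out / f"{s.site_id}.mask.csv", index=False)


def write_completed(
    completed: list[CompletedDataset], out_dir: str | Path
) -> None:
    """Completed datasets under ``out/<m>/<site>.csv``."""
    for c in completed:
        sub = Path(out_dir) / str(c.m)
        sub.mkdir(parents=True, exist_ok=True)
        for s in c.federation.sites:
            s.to_frame().to_csv(sub / f"{s.site_id}.csv", index=False)


_CONFIG_KEYS = {
    "data",
    "site_column",
    "outcome",
    "covariates",
    "binary_columns",
    "m_imputations",
    "between_iterations",
    "fit_rounds",
    "seed",
    "ci_level",
    "out",
    "write_completed",
}


def run_from_config(config_path: str | Path) -> "pd.DataFrame":
    """Execute impute -> analyze -> pool from a YAML configuration.

    Writes the pooled-results CSV, optional per-m completed datasets, and a
    run log (communication rounds, payload shapes, warnings, root seed)
    under the configured output directory.  Unknown config keys are an
    error — nothing is silently ignored.
    """
    cfg = yaml.safe_load(Path(config_path).read_text())
    unknown = set(cfg) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    schema = SiteTableSchema(
        outcome=cfg["outcome"],
        covariates=tuple(cfg.get("covariates", ())),
        site_column=cfg.get("site_column", "site"),
        binary_columns=tuple(cfg.get("binary_columns", ())),
    )
    out_dir = Path(cfg.get("out", "out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root_logger = logging.getLogger("d3mi")
    root_logger.addHandler(handler)
    root_logger.setLevel(logging.INFO)
    try:
        seed = int(cfg.get("seed", 0))
        logger.info("run_from_config: root seed %d", seed)
        fed = read_federation(cfg["data"], schema)
        specs = make_specs(fed, outcome=schema.outcome)
        completed = mice_run(
            fed,
            specs,
            M=int(cfg.get("m_imputations", 5)),
            n_between_iter=int(cfg.get("between_iterations", 10)),
            fit_rounds=int(cfg.get("fit_rounds", 1)),
            seed=seed,
        )
        model = GLMMModel(
            outcome=schema.outcome,
            covariates=schema.covariates,
            family=Family.gaussian,
            site_column=schema.site_column,
        )
        pooled = impute_analyze_pool(
            completed,
            model,
            fit_rounds=int(cfg.get("fit_rounds", 1)),
            ci_level=float(cfg.get("ci_level", 0.95)),
        )
        if cfg.get("write_completed", False):
            write_completed(completed, out_dir)
        result = pooled.to_frame()
        result.to_csv(out_dir / "pooled_results.csv", index=False)
        with open(out_dir / "sigma_u2.txt", "w") as fh:
            fh.write(f"sigma_u2_pooled={pooled.sigma_u2_pooled:.10g}\n")
        for c in completed:
            logger.info(
                "imputation m=%d: %d fit payloads, %d init payloads",
                c.m,
                c.federation.payload_count("fit"),
                c.federation.payload_count("init"),
            )
        return result
    finally:
        root_logger.removeHandler(handler)
        handler.close()
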