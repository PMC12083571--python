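"""The communication layer: in-process federation of sites.

Each site holds its own rows and answers summary requests; the aggregator
(:func:`dpql_fit`) sums the per-site Gram matrices and runs the PQL loop.
Because the REML solver consumes nothing but those sums, the federated fit
is numerically identical to the pooled fit — the protocol is lossless.

Sites never expose row-level data: the only outgoing payload is a
:class:`~d3mi.model.CrossProductSummary`, whose size depends on the number
of model columns, never on the number of rows.  Each site learns only its
own predicted random intercept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .families import Family, working_response
from .model import CrossProductSummary, GLMMFit, GLMMModel, make_summary, zero_summary
from .pql import run_pql

logger = logging.getLogger("d3mi.federation")


@dataclass
class SiteData:
    """One site's rows: column arrays plus the original missingness mask.

    ``values[c]`` holds the *current* value of column ``c`` (NaN where
    missing and not yet filled); ``mask[c]`` is True where the cell was
    missing in the source data.  The mask never changes; values at masked
    positions do (during imputation).
    """

    site_id: str
    values: dict[str, np.ndarray]
    mask: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.values.values()}
        if len(lengths) > 1:
            raise ValueError(f"site {self.site_id!r}: ragged columns")
        self.n = lengths.pop() if lengths else 0
        for c in self.values:
            self.values[c] = np.asarray(self.values[c], dtype=float)
            if c not in self.mask:
                self.mask[c] = np.zeros(self.n, dtype=bool)

    def copy(self) -> "SiteData":
        return SiteData(
            site_id=self.site_id,
            values={c: v.copy() for c, v in self.values.items()},
            mask={c: m.copy() for c, m in self.mask.items()},
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({c: v for c, v in self.values.items()})

    def design(self, columns: tuple[str, ...], rows: np.ndarray | None = None) -> np.ndarray:
        """Fixed-effect design [1 | columns] over selected rows."""
        sel = slice(None) if rows is None else rows
        cols = [np.ones(self.n)[sel]]
        for c in columns:
            if c not in self.values:
                raise KeyError(f"site {self.site_id!r}: unknown column {c!r}")
            cols.append(self.values[c][sel])
        return np.column_stack(cols)


def site_summary(
    site: SiteData,
    current_beta: np.ndarray | None,
    current_blup: float,
    model: GLMMModel,
    eligible: np.ndarray | None = None,
) -> CrossProductSummary:
    """One site's weighted cross-product payload at the given state.

    ``current_beta = None`` requests the ``eta = 0`` initialization payload.
    ``eligible`` restricts to a boolean row subset (e.g. rows where an
    imputation target is observed); zero eligible rows yield a valid
    all-zero summary with ``n = 0``.
    """
    for c in (model.outcome, *model.covariates):
        if c not in site.values:
            raise KeyError(f"site {site.site_id!r}: schema mismatch, no column {c!r}")
    rows = None if eligible is None else np.asarray(eligible, dtype=bool)
    n_rows = site.n if rows is None else int(rows.sum())
    if n_rows == 0:
        return zero_summary(model.n_coef, site.site_id)
    X = site.design(model.covariates, rows)
    sel = slice(None) if rows is None else rows
    y = site.values[model.outcome][sel]
    if current_beta is None:
        eta = np.zeros(n_rows)
    else:
        eta = X @ current_beta + current_blup
    z, w = working_response(y, eta, model.family)
    return make_summary(X, z, w, site.site_id)


class Federation:
    """An ordered collection of sites behind the summary interface.

    The column schema (names, families, 0/1 coding of binary columns) is
    shared by all sites — it is broadcast once, before any fitting.  The
    federation keeps an append-only payload log for communication audits.
    """

    def __init__(self, sites: list[SiteData], binary_columns: set[str] | None = None):
        ids = [s.site_id for s in sites]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate site ids")
        if sites:
            schema = tuple(sites[0].values.keys())
            for s in sites[1:]:
                if tuple(s.values.keys()) != schema:
                    raise ValueError(
                        f"site {s.site_id!r} does not conform to the shared schema"
                    )
        self.sites = list(sites)
        self.binary_columns = set(binary_columns or ())
        self.payload_log: list[dict] = []
        for s in self.sites:
            if s.n < 2:
                logger.warning("site %s has fewer than 2 rows", s.site_id)

    # -- basic accessors -------------------------------------------------
    @property
    def site_ids(self) -> list[str]:
        return [s.site_id for s in self.sites]

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_total(self) -> int:
        return sum(s.n for s in self.sites)

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(self.sites[0].values.keys()) if self.sites else ()

    def site(self, site_id: str) -> SiteData:
        for s in self.sites:
            if s.site_id == site_id:
                return s
        raise KeyError(site_id)

    def n_masked(self, column: str | None = None) -> int:
        cols = [column] if column else list(self.columns)
        return int(sum(s.mask[c].sum() for s in self.sites for c in cols))

    def copy(self) -> "Federation":
        fed = Federation([s.copy() for s in self.sites], set(self.binary_columns))
        return fed

    def to_frame(self, site_column: str = "site") -> pd.DataFrame:
        frames = []
        for s in self.sites:
            df = s.to_frame()
            df.insert(0, site_column, s.site_id)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    # -- communication ---------------------------------------------------
    def request_summaries(
        self,
        model: GLMMModel,
        beta: np.ndarray | None,
        blups: dict[str, float],
        eligible: dict[str, np.ndarray] | None = None,
        kind: str = "fit",
    ) -> list[CrossProductSummary]:
        """One round of one-way communication: one payload per site."""
        out = []
        for s in self.sites:
            sm = site_summary(
                s,
                beta,
                blups.get(s.site_id, 0.0),
                model,
                None if eligible is None else eligible.get(s.site_id),
            )
            self.payload_log.append(
                {"kind": kind, "site": s.site_id, "shape": sm.gram.shape, "n": sm.n}
            )
            out.append(sm)
        return out

    def payload_count(self, kind: str = "fit") -> int:
        return sum(1 for rec in self.payload_log if rec["kind"] == kind)


def federation_from_frame(
    data: pd.DataFrame,
    site_column: str = "site",
    binary_columns: set[str] | None = None,
) -> Federation:
    """Build a federation from a pooled table with a site-identifier column.

    NaN cells become masked cells; row order within a site is preserved and
    site order follows first appearance.
    """
    sites = []
    for site_id, grp in data.groupby(site_column, sort=False):
        values, mask = {}, {}
        for c in data.columns:
            if c == site_column:
                continue
            col = grp[c].to_numpy(dtype=float)
            values[c] = col
            mask[c] = np.isnan(col)
        sites.append(SiteData(site_id=str(site_id), values=values, mask=mask))
    return Federation(sites, binary_columns)


def dpql_fit(
    federation: Federation,
    model: GLMMModel,
    n_outer_iter: int = 1,
    tol: float = 1e-6,
    eligible: dict[str, np.ndarray] | None = None,
) -> GLMMFit:
    """Distributed PQL: aggregate site summaries and solve centrally.

    Per outer iteration the aggregator makes exactly one summary request per
    site and sums the Gram matrices; the result equals :func:`d3mi.pql.fit_pql`
    on the pooled rows.  ``n_outer_iter = 1`` is the communication-efficient
    default (exact for the gaussian family).  For the binomial family one
    extra initialization round (logged with kind ``"init"``) supplies the
    no-random-effect GLM starting value.
    """
    if n_outer_iter < 1:
        raise ValueError("n_outer_iter must be >= 1")
    if federation.n_sites < 2:
        logger.warning(
            "fewer than 2 sites: sigma_u2 is weakly identified and may hit 0"
        )

    def summary_fn(beta, blups):
        kind = "init" if beta is None else "fit"
        return federation.request_summaries(
            model, beta, blups, eligible=eligible, kind=kind
        )

    return run_pql(summary_fn, model, max_outer_iter=n_outer_iter, tol=tol)
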