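"""Parameter sweeps, published-table reproduction and unstated-parameter search.

The published wall-quantity tables state only part of the inputs behind
each row (the heat-transfer table omits the volume fractions and the
domain edge; the skin-friction table omits the Prandtl number and the
edge). :func:`identify_unstated_params` searches a candidate grid for
the assignment that best matches a set of printed rows, and
:func:`reproduce_tables` emits side-by-side computed/printed tables at
either the package defaults or an identified assignment.
"""

from __future__ import annotations

import itertools
import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .similarity import SimilarityParams
from .solver import SolverError, SolverOptions, solve_profile
from .walls import nusselt, skin_friction

__all__ = [
    "SweepConfig",
    "TableRecord",
    "IdentificationResult",
    "TABLE2_ROWS",
    "TABLE3_ROWS",
    "run_sweep",
    "records_to_frame",
    "reproduce_tables",
    "identify_unstated_params",
    "parse_config",
]

# Published wall-quantity rows used for reproduction and identification.
# Each entry: stated inputs for that row plus the printed value.
# Heat-transfer table: (gamma, Pr) -> -(k/k_f) theta'(0) as printed.
TABLE2_ROWS = (
    {"gamma": 0.1, "pr": 3.0, "printed": -1.4544},
    {"gamma": 0.12, "pr": 3.0, "printed": -1.4059},
    {"gamma": 0.14, "pr": 3.0, "printed": -1.3552},
    {"gamma": 0.1, "pr": 3.0, "printed": -1.4544},
    {"gamma": 0.1, "pr": 3.5, "printed": -1.8724},
    {"gamma": 0.1, "pr": 4.0, "printed": -2.2959},
)
# Skin-friction table: (gamma, phi) with phi applied to both species.
TABLE3_ROWS = (
    {"gamma": 0.1, "phi": 0.01, "printed": -2.0502},
    {"gamma": 0.12, "phi": 0.01, "printed": -2.0012},
    {"gamma": 0.14, "phi": 0.01, "printed": -1.9566},
    {"gamma": 0.1, "phi": 0.01, "printed": -2.0502},
    {"gamma": 0.1, "phi": 0.15, "printed": -2.4421},
    {"gamma": 0.1, "phi": 0.2, "printed": -2.8603},
)

# Reproduction-run defaults for the inputs the published tables omit.
DEFAULTS = {"phi1": 0.05, "phi2": 0.05, "eta_edge": 1.0, "pr": 3.0,
            "closure": "stretching-wall"}


@dataclass(frozen=True)
class SweepConfig:
    """Cross-product sweep over the dimensionless inputs."""

    gamma: tuple = (0.1,)
    pr: tuple = (3.0,)
    phi1: tuple = (0.05,)
    phi2: tuple = (0.05,)
    eta_edge: tuple = (1.0,)
    closure: str = "stretching-wall"
    options: SolverOptions = field(default_factory=SolverOptions)
    quiet: bool = False

    def __post_init__(self) -> None:
        for name in ("gamma", "pr", "phi1", "phi2", "eta_edge"):
            values = getattr(self, name)
            if len(values) == 0:
                raise ValueError(f"parameter list {name!r} must be non-empty")

    @property
    def size(self) -> int:
        return (
            len(self.gamma) * len(self.pr) * len(self.phi1)
            * len(self.phi2) * len(self.eta_edge)
        )


@dataclass(frozen=True)
class TableRecord:
    """One sweep row: inputs, wall outputs, diagnostics."""

    gamma: float
    pr: float
    phi1: float
    phi2: float
    eta_edge: float
    closure: str
    Fpp0: float
    thetap0: float
    cf_scaled: float
    nu_scaled: float
    converged: bool
    max_residual: float
    n_nodes: int
    failure: str = ""


_CSV_COLUMNS = [
    "gamma", "pr", "phi1", "phi2", "eta_edge", "closure",
    "Fpp0", "thetap0", "cf_scaled", "nu_scaled",
    "converged", "max_residual", "n_nodes", "failure",
]


class _SolveCache:
    """Memoised wall quantities keyed by the full parameter tuple."""

    def __init__(self, options: SolverOptions | None = None):
        self.options = options or SolverOptions()
        self._cache: dict[tuple, tuple] = {}

    def wall(self, gamma, pr, phi1, phi2, eta_edge, closure):
        key = (gamma, pr, phi1, phi2, eta_edge, closure)
        if key not in self._cache:
            params = SimilarityParams(
                gamma=gamma, pr=pr, phi1=phi1, phi2=phi2,
                eta_edge=eta_edge, closure=closure,
            )
            profile = solve_profile(params, self.options)
            mix = params.mixture
            self._cache[key] = (
                skin_friction(profile, mix),
                nusselt(profile, mix),
                profile,
            )
        return self._cache[key]


def run_sweep(config: SweepConfig, csv_path=None) -> list[TableRecord]:
    """Run the cross-product sweep in lexicographic parameter order.

    Solver failures are recorded (flagged, with the failure message) and
    the sweep continues. One structured log line per solve goes to
    standard error unless ``config.quiet``.
    """
    if not config.quiet:
        print(f"sweep: {config.size} solves", file=sys.stderr)
    records = []
    for gamma, pr, phi1, phi2, eta_edge in itertools.product(
        config.gamma, config.pr, config.phi1, config.phi2, config.eta_edge
    ):
        params = SimilarityParams(
            gamma=gamma, pr=pr, phi1=phi1, phi2=phi2,
            eta_edge=eta_edge, closure=config.closure,
        )
        try:
            profile = solve_profile(params, config.options)
            mix = params.mixture
            rec = TableRecord(
                gamma=gamma, pr=pr, phi1=phi1, phi2=phi2,
                eta_edge=eta_edge, closure=config.closure,
                Fpp0=profile.Fpp0, thetap0=profile.thetap0,
                cf_scaled=skin_friction(profile, mix),
                nu_scaled=nusselt(profile, mix),
                converged=True,
                max_residual=profile.diagnostics.max_residual,
                n_nodes=profile.diagnostics.n_nodes,
            )
        except SolverError as err:
            rec = TableRecord(
                gamma=gamma, pr=pr, phi1=phi1, phi2=phi2,
                eta_edge=eta_edge, closure=config.closure,
                Fpp0=np.nan, thetap0=np.nan,
                cf_scaled=np.nan, nu_scaled=np.nan,
                converged=False, max_residual=np.nan, n_nodes=0,
                failure=str(err),
            )
        if not config.quiet:
            print(
                f"solve gamma={gamma:g} pr={pr:g} phi1={phi1:g} phi2={phi2:g} "
                f"eta_edge={eta_edge:g} Fpp0={rec.Fpp0:.6g} thetap0={rec.thetap0:.6g} "
                f"residual={rec.max_residual:.3g} nodes={rec.n_nodes}",
                file=sys.stderr,
            )
        records.append(rec)
    if csv_path is not None:
        records_to_frame(records).to_csv(csv_path, index=False, float_format="%.12g")
    return records


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records], columns=_CSV_COLUMNS)


def _row_quantity(cache: _SolveCache, quantity: str, assignment: dict, row: dict) -> float:
    """Computed cf or nu for one printed row under a candidate assignment.

    Row-stated parameters take precedence over the assignment; a bare
    ``phi`` in the row sets both volume fractions.
    """
    merged = dict(DEFAULTS)
    merged.update(assignment)
    merged.update({k: v for k, v in row.items() if k not in ("printed", "quantity")})
    if "phi" in merged:
        phi = merged.pop("phi")
        merged["phi1"] = phi
        merged["phi2"] = phi
    cf, nu, _ = cache.wall(
        merged["gamma"], merged["pr"], merged["phi1"], merged["phi2"],
        merged["eta_edge"], merged["closure"],
    )
    return cf if quantity == "cf" else nu


@dataclass(frozen=True)
class IdentificationResult:
    assignment: dict
    misfit: float
    table: pd.DataFrame = field(compare=False)
    tied: tuple = ()


def identify_unstated_params(
    printed_rows,
    candidates: dict,
    quantity: str,
    options: SolverOptions | None = None,
) -> IdentificationResult:
    """Exhaustive minimax search for the inputs a published table omits.

    ``printed_rows`` is a sequence of dicts with the row-stated inputs
    plus ``printed``; ``candidates`` maps parameter names (``phi``,
    ``eta_edge``, ``pr``) to value lists; ``quantity`` is ``"cf"`` or
    ``"nu"``. The misfit of an assignment is the maximum absolute
    deviation between computed and printed values over the rows. Returns
    the arg-min in deterministic grid order, the full misfit table, and
    any exactly-tied assignments.
    """
    if quantity not in ("cf", "nu"):
        raise ValueError(f"quantity must be 'cf' or 'nu', got {quantity!r}")
    names = list(candidates)
    grids = [list(candidates[n]) for n in names]
    if not names or any(len(g) == 0 for g in grids):
        raise ValueError("candidate grid must be non-empty")
    cache = _SolveCache(options)
    rows = []
    best = None  # (index, assignment, misfit)
    for index, values in enumerate(itertools.product(*grids)):
        assignment = dict(zip(names, values))
        try:
            deviations = [
                abs(_row_quantity(cache, quantity, assignment, row) - row["printed"])
                for row in printed_rows
            ]
            misfit = max(deviations)
        except SolverError:
            misfit = np.inf
        rows.append({**assignment, "misfit": misfit})
        if best is None or misfit < best[2]:
            best = (index, assignment, misfit)
    table = pd.DataFrame(rows)
    tied = tuple(
        tuple(r[n] for n in names)
        for i, r in enumerate(rows)
        if r["misfit"] == best[2] and i != best[0]
    )
    return IdentificationResult(assignment=best[1], misfit=best[2], table=table, tied=tied)


def reproduce_tables(
    overrides: dict | None = None,
    options: SolverOptions | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Computed-vs-printed reproduction of the two published wall tables.

    ``overrides`` replaces entries of the reproduction defaults
    (``phi1``, ``phi2``, ``eta_edge``, ``pr``, ``closure``), e.g. with an
    identification result. Returns (heat-transfer table, skin-friction
    table); each carries the printed column under its published header
    text alongside the computed value and absolute difference.
    """
    settings = dict(DEFAULTS)
    if overrides:
        settings.update(overrides)
        if "phi" in settings:
            phi = settings.pop("phi")
            settings["phi1"] = phi
            settings["phi2"] = phi
    cache = _SolveCache(options)

    nu_rows = []
    for row in TABLE2_ROWS:
        computed = _row_quantity(cache, "nu", settings, row)
        nu_rows.append(
            {
                "gamma": row["gamma"],
                "Pr": row["pr"],
                "-(k_nf/k_f) theta'(0) [printed]": row["printed"],
                "computed nu_scaled": computed,
                "abs_diff": abs(computed - row["printed"]),
            }
        )
    cf_rows = []
    for row in TABLE3_ROWS:
        computed = _row_quantity(cache, "cf", settings, row)
        cf_rows.append(
            {
                "gamma": row["gamma"],
                "phi": row["phi"],
                "(1/2) Cf Re [printed]": row["printed"],
                "computed cf_scaled": computed,
                "abs_diff": abs(computed - row["printed"]),
            }
        )
    table_nu = pd.DataFrame(nu_rows)
    table_cf = pd.DataFrame(cf_rows)
    table_nu.attrs["settings"] = dict(settings)
    table_cf.attrs["settings"] = dict(settings)
    return table_nu, table_cf


def parse_config(path) -> dict:
    """Parse a flat key=value config file.

    Comma-separated values become lists of floats where possible;
    ``#`` starts a comment. Keys mirror the CLI flags (dashes or
    underscores accepted).
    """
    out: dict = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            key = key.replace("-", "_")
            items = [v.strip() for v in value.split(",") if v.strip()]
            parsed = []
            for item in items:
                try:
                    parsed.append(float(item))
                except ValueError:
                    parsed.append(item)
            out[key] = parsed[0] if len(parsed) == 1 else parsed
    return out
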