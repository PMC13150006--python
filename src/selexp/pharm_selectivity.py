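"""Concentration–response modelling and fold-selectivity reporting.

Agonist potency is summarised as pEC50 — the negative decadic logarithm of
the molar concentration producing half-maximal response — obtained by
fitting a 3-parameter logistic (Hill slope fixed at 1):

    response(c) = basal + (emax − basal) / (1 + 10^(−(log10 c + pEC50)))

Selectivity between two conditions (two agonists at one receptor, or one
agonist at mutant vs wild-type) is the potency ratio

    fold = 10^(pEC50_a − pEC50_b)

reported rounded to two significant figures, the convention used for
published fold values; full precision is retained in machine output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import DomainError, FitError

# ---------------------------------------------------------------------------
# Model


def logistic_response(
    c: float | np.ndarray, basal: float, emax: float, pec50: float
) -> float | np.ndarray:
    """3-parameter logistic response at molar concentration ``c`` (> 0)."""
    c = np.asarray(c, dtype=float)
    if np.any(c <= 0):
        raise DomainError("concentrations must be strictly positive (molar)")
    logc = np.log10(c)
    out = basal + (emax - basal) / (1.0 + 10.0 ** (-(logc + pec50)))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ConcentrationResponseCurve:
    """One replicate of a concentration–response experiment."""

    ligand: str
    receptor: str
    concentrations: np.ndarray  # molar, strictly positive
    responses: np.ndarray  # normalized % of WT max
    replicate: str | int = 0

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        resp = np.asarray(self.responses, dtype=float)
        if conc.shape != resp.shape or conc.ndim != 1:
            raise DomainError("concentrations and responses must be equal-length 1-D")
        if np.any(conc <= 0):
            raise DomainError("concentrations must be strictly positive")
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "responses", resp)

    @property
    def log_span(self) -> float:
        return float(np.log10(self.concentrations.max() / self.concentrations.min()))


@dataclass(frozen=True)
class LogisticFit:
    basal: float
    emax: float
    pec50: float
    converged: bool
    residual_norm: float
    reason: str = ""


# ---------------------------------------------------------------------------
# Fitting

_FLAT_TOLERANCE = 1e-9


def fit_curve(
    curve: ConcentrationResponseCurve,
    *,
    pec50_grid: Sequence[float] = tuple(range(4, 11)),
    jitter: float = 0.25,
    n_jitter: int = 0,
    seed: int = 0,
    constrain_increasing: bool = False,
) -> LogisticFit:
    """Least-squares 3-parameter logistic fit with multi-start initialisation.

    Starts are taken on a pEC50 grid (default 4–10, step 1) plus
    seed-controlled jittered repeats; the best residual norm wins.  Requires
    at least 4 points spanning at least 2 log units of concentration.  A flat
    response (range below tolerance relative to its magnitude) returns a
    non-converged fit with a named reason rather than a spurious optimum.
    """
    if curve.concentrations.size < 4:
        raise FitError("need at least 4 concentration points to fit")
    if curve.log_span < 2.0:
        raise FitError(
            f"concentration span {curve.log_span:.2f} log units < 2 required"
        )
    resp = curve.responses
    span = float(resp.max() - resp.min())
    scale = max(abs(resp).max(), 1.0)
    if span < _FLAT_TOLERANCE * scale or span == 0.0:
        return LogisticFit(
            float(resp.mean()), float(resp.mean()), math.nan, False,
            float(np.linalg.norm(resp - resp.mean())), reason="flat-response",
        )
    logc = np.log10(curve.concentrations)

    def residuals(params: np.ndarray) -> np.ndarray:
        basal, emax, pec50 = params
        pred = basal + (emax - basal) / (1.0 + 10.0 ** (-(logc + pec50)))
        return pred - resp

    rng = np.random.default_rng(seed)
    lower = np.array([-np.inf, -np.inf, 0.0])
    upper = np.array([np.inf, np.inf, 14.0])
    starts = []
    for p0 in pec50_grid:
        starts.append((float(resp.min()), float(resp.max()), float(p0)))
        for _ in range(n_jitter):
            starts.append(
                (float(resp.min()), float(resp.max()),
                 float(np.clip(p0 + rng.normal(0.0, jitter), 0.0, 14.0)))
            )
    best = None
    for start in starts:
        try:
            sol = least_squares(residuals, np.array(start), bounds=(lower, upper))
        except ValueError:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return LogisticFit(math.nan, math.nan, math.nan, False, math.inf,
                           reason="optimizer-failure")
    basal, emax, pec50 = best.x
    if constrain_increasing and emax < basal:
        basal, emax = emax, basal
    converged = bool(best.success) and math.isfinite(pec50)
    return LogisticFit(
        float(basal), float(emax), float(pec50), converged,
        float(np.sqrt(2.0 * best.cost)),
    )


# ---------------------------------------------------------------------------
# Fold selectivity


def round_sf(x: float, sig_figs: int = 2) -> float:
    """Round to ``sig_figs`` significant figures."""
    if x == 0 or not math.isfinite(x):
        return x
    digits = sig_figs - 1 - int(math.floor(math.log10(abs(x))))
    return round(x, digits)


def fold_selectivity(pec50_a: float, pec50_b: float) -> tuple[float, float]:
    """Potency ratio ``10^(pEC50_a − pEC50_b)``.

    Returns the full-precision fold and its value rounded to two significant
    figures (the published reporting convention).
    """
    if not (math.isfinite(pec50_a) and math.isfinite(pec50_b)):
        raise DomainError("fold selectivity needs finite pEC50 values")
    fold = 10.0 ** (pec50_a - pec50_b)
    return fold, round_sf(fold, 2)


# ---------------------------------------------------------------------------
# Profiles


@dataclass(frozen=True)
class SelectivityProfile:
    receptor: str
    pec50: Mapping[str, float]
    folds: Mapping[tuple[str, str], float]  # (ligand_i, ligand_j) -> 10^Δ
    preferred: tuple[str, ...]  # highest-pEC50 ligand(s); >1 on ties


def profile_report(
    pec50_table: pd.DataFrame,
    wt_map: Mapping[str, str] | None = None,
    tie_tolerance: float = 1e-9,
) -> tuple[list[SelectivityProfile], pd.DataFrame]:
    """Assemble selectivity profiles from a pEC50 table.

    ``pec50_table`` needs columns ``receptor``, ``ligand``, ``pec50``.  Per
    receptor, all pairwise ligand folds and the preferred ligand(s) are
    reported; with ``wt_map`` (mutant receptor → wild-type receptor) the
    mutant-vs-WT fold change per shared ligand is added.  Returns the
    profiles and a tidy DataFrame with columns ``receptor, comparison, a, b,
    fold, fold_2sf``.
    """
    required = {"receptor", "ligand", "pec50"}
    if not required.issubset(pec50_table.columns):
        raise DomainError(f"pec50 table must have columns {sorted(required)}")
    profiles: list[SelectivityProfile] = []
    rows: list[dict] = []
    by_receptor = {
        rec: dict(zip(grp["ligand"], grp["pec50"]))
        for rec, grp in pec50_table.groupby("receptor", sort=False)
    }
    for receptor, pec50s in by_receptor.items():
        ligands = list(pec50s)
        folds: dict[tuple[str, str], float] = {}
        for i in ligands:
            for j in ligands:
                if i == j:
                    continue
                fold, fold2 = fold_selectivity(pec50s[i], pec50s[j])
                folds[(i, j)] = fold
                rows.append(
                    {"receptor": receptor, "comparison": "ligand", "a": i,
                     "b": j, "fold": fold, "fold_2sf": fold2}
                )
        top = max(pec50s.values())
        preferred = tuple(
            sorted(l for l, v in pec50s.items() if abs(v - top) <= tie_tolerance)
        )
        profiles.append(SelectivityProfile(receptor, dict(pec50s), folds, preferred))
    if wt_map:
        for mutant, wt in wt_map.items():
            if mutant not in by_receptor or wt not in by_receptor:
                import warnings

                warnings.warn(
                    f"wt_map entry {mutant!r}->{wt!r} missing from table; skipped",
                    stacklevel=2,
                )
                continue
            for ligand in by_receptor[mutant]:
                if ligand not in by_receptor[wt]:
                    continue
                fold, fold2 = fold_selectivity(
                    by_receptor[mutant][ligand], by_receptor[wt][ligand]
                )
                rows.append(
                    {"receptor": mutant, "comparison": f"vs-WT({wt})",
                     "a": ligand, "b": ligand, "fold": fold, "fold_2sf": fold2}
                )
    return profiles, pd.DataFrame(rows)


def fit_pec50_table(
    curves: pd.DataFrame,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit every (receptor, ligand) group of a tidy curve table.

    ``curves`` needs columns ``receptor, ligand, replicate, concentration_M,
    response``; replicates are pooled into one fit per (receptor, ligand).
    Returns a DataFrame with ``receptor, ligand, pec50, basal, emax,
    converged, residual_norm``.
    """
    required = {"receptor", "ligand", "replicate", "concentration_M", "response"}
    if not required.issubset(curves.columns):
        raise DomainError(f"curve table must have columns {sorted(required)}")
    rows = []
    for (receptor, ligand), grp in curves.groupby(["receptor", "ligand"], sort=False):
        curve = ConcentrationResponseCurve(
            ligand=str(ligand), receptor=str(receptor),
            concentrations=grp["concentration_M"].to_numpy(),
            responses=grp["response"].to_numpy(),
            replicate="pooled",
        )
        fit = fit_curve(curve, seed=seed)
        rows.append(
            {"receptor": receptor, "ligand": ligand, "pec50": fit.pec50,
             "basal": fit.basal, "emax": fit.emax, "converged": fit.converged,
             "residual_norm": fit.residual_norm}
        )
    return pd.DataFrame(rows)
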