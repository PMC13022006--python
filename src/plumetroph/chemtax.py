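"""ChemTax-style pigment unmixing of the microalgae community.

Chemotaxonomy assumes each microalgal class carries a characteristic
pigment:chlorophyll-a weight-ratio signature.  A sample's pigment vector
``s`` (µg L⁻¹) is modelled as a non-negative combination of class
signatures: ``s ≈ cᵀ F`` with ``F`` the classes × pigments ratio matrix and
``c`` the per-class chlorophyll-a contributions (the Chl a column of F is
identically 1).  Fitting is per-sample non-negative least squares under
pigment column weighting.

The full procedure follows the classic three-run randomisation: 60 ratio
matrices obtained by ±35% perturbation of the nonzero entries are each
locally optimised against the data; the next run re-seeds from the
element-wise mean of the six best matrices; the composition under the best
final matrix is reported as percent of total chlorophyll a.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

PIGMENTS = (
    "Chl b",
    "But Fuco",
    "Hex Fuco",
    "Allo",
    "Fuco",
    "Perid",
    "Zea",
    "DV Chl b",
    "Chl c1+c2",
    "Chl c3",
    "Lut",
    "Neo",
    "Viola",
    "Pras",
    "Chl a",
)

CLASSES = (
    "Cyanobacteria1",
    "Cyanobacteria2",
    "Cyanobacteria4",
    "Prasinophytes3",
    "Cryptophytes",
    "Diatoms1",
    "Haptophytes6",
    "Dinoflagellates1",
)

# Published initial pigment:chl-a ratio matrix (rows follow CLASSES,
# columns follow PIGMENTS).
_INITIAL = np.array([
    [0,     0,     0,     0,     0,     0,     0.105, 0,     0,     0,     0,     0,     0,     0,     1],
    [0,     0,     0,     0,     0,     0,     0.453, 0,     0,     0,     0,     0,     0,     0,     1],
    [0.495, 0,     0,     0,     0,     0,     0.224, 0.495, 0,     0,     0,     0,     0,     0,     1],
    [0.368, 0,     0,     0,     0,     0,     0.033, 0,     0,     0,     0.013, 0.051, 0.035, 0.145, 1],
    [0,     0,     0,     0.359, 0,     0,     0,     0,     0.145, 0,     0,     0,     0,     0,     1],
    [0,     0,     0,     0,     0.711, 0,     0,     0,     0.074, 0,     0,     0,     0,     0,     1],
    [0,     0.004, 0.237, 0,     0.066, 0,     0,     0,     0.178, 0.156, 0,     0,     0,     0,     1],
    [0,     0,     0,     0,     0,     0.541, 0,     0,     0.197, 0,     0,     0,     0,     0,     1],
])

# Converged ratio matrix yielded by the published three-run analysis.
_FINAL = np.array([
    [0,     0,     0,     0,     0,     0,     0.101, 0,     0,     0,     0,     0,     0,     0,     1],
    [0,     0,     0,     0,     0,     0,     1.343, 0,     0,     0,     0,     0,     0,     0,     1],
    [0.432, 0,     0,     0,     0,     0,     0.203, 0.363, 0,     0,     0,     0,     0,     0,     1],
    [0.605, 0,     0,     0,     0,     0,     0.035, 0,     0,     0,     0.013, 0.047, 0.035, 0.082, 1],
    [0,     0,     0,     0.322, 0,     0,     0,     0,     0.129, 0,     0,     0,     0,     0,     1],
    [0,     0,     0,     0,     0.609, 0,     0,     0,     0.098, 0,     0,     0,     0,     0,     1],
    [0,     0.009, 0.488, 0,     0.096, 0,     0,     0,     0.215, 0.211, 0,     0,     0,     0,     1],
    [0,     0,     0,     0,     0,     0.579, 0,     0,     0.236, 0,     0,     0,     0,     0,     1],
])


def initial_ratio_matrix() -> pd.DataFrame:
    """Published initial ratio matrix (classes × pigments)."""
    return pd.DataFrame(_INITIAL.copy(), index=list(CLASSES), columns=list(PIGMENTS))


def final_ratio_matrix() -> pd.DataFrame:
    """Published converged ratio matrix (classes × pigments)."""
    return pd.DataFrame(_FINAL.copy(), index=list(CLASSES), columns=list(PIGMENTS))


def _validate_ratio_matrix(F: pd.DataFrame) -> None:
    if (F.to_numpy(float) < 0).any():
        raise ValueError("ratio matrix entries must be non-negative")
    if "Chl a" not in F.columns:
        raise ValueError("ratio matrix must carry a 'Chl a' column")
    if not np.allclose(F["Chl a"].to_numpy(float), 1.0):
        raise ValueError("Chl a column of a ratio matrix must be identically 1")


def _pigment_columns(S: pd.DataFrame, F: pd.DataFrame) -> list[str]:
    missing = [p for p in F.columns if p not in S.columns]
    if missing:
        raise ValueError(f"pigment table lacks columns: {missing}")
    return list(F.columns)


def _column_weights(X: np.ndarray, weighting: str) -> np.ndarray:
    """Per-pigment weights: inverse RMS over samples ('rms') or ones."""
    if weighting == "none":
        return np.ones(X.shape[1])
    if weighting != "rms":
        raise ValueError("weighting must be 'rms' or 'none'")
    rms = np.sqrt(np.mean(X**2, axis=0))
    w = np.ones_like(rms)
    nz = rms > 0
    w[nz] = 1.0 / rms[nz]
    return w


def _solve(X: np.ndarray, A: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, float]:
    """NNLS coefficients and weighted RMS objective, numpy fast path."""
    Aw = (A * w).T
    coefs = np.zeros((X.shape[0], A.shape[0]))
    resid2 = 0.0
    for i, row in enumerate(X):
        if not row.any():
            continue
        c, _ = nnls(Aw, row * w)
        coefs[i] = c
        resid2 += float(np.sum((Aw @ c - row * w) ** 2))
    return coefs, float(np.sqrt(resid2 / X.size))


def fit_composition(
    S: pd.DataFrame,
    F: pd.DataFrame,
    weighting: str = "rms",
) -> tuple[pd.DataFrame, float]:
    """Unmix pigment samples onto class signatures by non-negative least squares.

    Parameters
    ----------
    S : samples × pigments concentration table (µg L⁻¹); must contain every
        pigment column of ``F``; extra (metadata) columns are ignored.
    F : classes × pigments ratio matrix with a unit Chl a column.
    weighting : 'rms' scales each pigment column by the inverse of its RMS
        over samples before fitting so abundant pigments do not dominate;
        'none' fits raw concentrations.

    Returns
    -------
    composition : samples × classes table with chl-a contributions
        (``<class>`` columns, µg chl a L⁻¹) and percent shares
        (``<class>_pct``), plus ``total_chla``.
    objective : weighted root-mean-square residual over all sample × pigment
        cells.
    """
    _validate_ratio_matrix(F)
    pigs = _pigment_columns(S, F)
    if len(pigs) < 2:
        raise ValueError("need at least one pigment besides Chl a")
    X = S[pigs].to_numpy(float)
    if (X < 0).any():
        raise ValueError("pigment concentrations must be non-negative")
    A = F[pigs].to_numpy(float)  # classes x pigments
    w = _column_weights(X, weighting)
    for i, row in enumerate(X):
        if not row.any():
            warnings.warn(
                f"sample {S.index[i]!r}: all pigments zero; composition set to zero",
                stacklevel=2,
            )
    coefs, objective = _solve(X, A, w)
    comp = pd.DataFrame(coefs, index=S.index, columns=list(F.index))
    total = comp.sum(axis=1)
    comp["total_chla"] = total
    for cls in F.index:
        with np.errstate(invalid="ignore", divide="ignore"):
            comp[f"{cls}_pct"] = np.where(total > 0, comp[cls] / total * 100.0, 0.0)
    return comp, objective


def perturb_ratio_matrix(
    F0: pd.DataFrame, magnitude: float = 0.35, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """Randomise the nonzero non-Chl-a ratios by independent ±``magnitude`` factors.

    Each such entry is multiplied by ``1 + u`` with ``u ~ Uniform(−m, +m)``;
    the Chl a column and structural zeros are preserved.  Deterministic for
    a given seed.
    """
    if not (0 <= magnitude < 1):
        raise ValueError("magnitude must lie in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    _validate_ratio_matrix(F0)
    F = F0.copy()
    vals = F.to_numpy(float)
    mask = vals > 0
    mask[:, list(F.columns).index("Chl a")] = False
    u = rng.uniform(-magnitude, magnitude, size=vals.shape)
    vals = np.where(mask, vals * (1.0 + u), vals)
    return pd.DataFrame(vals, index=F.index, columns=F.columns)


def optimize_ratio_matrix(
    S: pd.DataFrame,
    F_init: pd.DataFrame,
    max_iter: int = 20,
    bound: float = 0.50,
    step: float = 0.10,
    weighting: str = "rms",
    rel_tol: float = 1e-6,
) -> tuple[pd.DataFrame, list[float]]:
    """Greedy local refinement of a ratio matrix against pigment data.

    Sweeps the nonzero non-Chl-a entries, proposing multiplicative steps
    ``×(1±step)``; a step is accepted only if the :func:`fit_composition`
    objective decreases, and entries stay within ``[1−bound, 1+bound]``
    times their initial value.  Stops after ``max_iter`` sweeps or when a
    full sweep improves the objective by a relative factor below
    ``rel_tol``.  The returned trace of objective values (one per evaluated
    state, starting from the initial fit) is non-increasing.
    """
    _validate_ratio_matrix(F_init)
    pigs = _pigment_columns(S, F_init)
    X = S[pigs].to_numpy(float)
    w = _column_weights(X, weighting)
    A = F_init[pigs].to_numpy(float).copy()
    init_vals = A.copy()
    lo = init_vals * (1.0 - bound)
    hi = init_vals * (1.0 + bound)
    chla_j = pigs.index("Chl a")
    entries = [
        (i, j)
        for i in range(A.shape[0])
        for j in range(A.shape[1])
        if init_vals[i, j] > 0 and j != chla_j
    ]
    _, obj = _solve(X, A, w)
    trace = [obj]
    for _ in range(max_iter):
        sweep_start = obj
        for i, j in entries:
            cur = A[i, j]
            best_val, best_obj = cur, obj
            for factor in (1.0 - step, 1.0 + step):
                cand = float(np.clip(cur * factor, lo[i, j], hi[i, j]))
                if cand == cur:
                    continue
                A[i, j] = cand
                _, cand_obj = _solve(X, A, w)
                # require a real improvement, not floating-point jitter
                if best_obj - cand_obj > 1e-12:
                    best_val, best_obj = cand, cand_obj
            A[i, j] = best_val
            if best_obj < obj:
                obj = best_obj
                trace.append(obj)
        if sweep_start == 0 or (sweep_start - obj) / max(sweep_start, 1e-300) < rel_tol:
            break
    F = F_init.copy()
    F[pigs] = A
    return F, trace


@dataclass
class ChemtaxDiagnostics:
    """Per-run best objectives and the objective of every optimised matrix."""

    best_objectives: list[float]
    run_objectives: list[list[float]]


def chemtax_run(
    S: pd.DataFrame,
    F0: pd.DataFrame | None = None,
    n_random: int = 60,
    n_runs: int = 3,
    n_best: int = 6,
    magnitude: float = 0.35,
    seed: int = 0,
    max_iter: int = 20,
    bound: float = 0.50,
    weighting: str = "rms",
) -> tuple[pd.DataFrame, pd.DataFrame, ChemtaxDiagnostics]:
    """Full randomised ChemTax analysis.

    Each run draws ``n_random`` perturbed ratio matrices, optimises each
    against the data, and ranks them by objective (ties by generation
    index); the next run re-seeds from the element-wise mean of the
    ``n_best`` optimised matrices.  Returns the composition under the best
    matrix of the last run, that matrix, and per-run diagnostics.
    Reproducible for a given ``seed``.
    """
    if F0 is None:
        F0 = initial_ratio_matrix()
    if n_best > n_random:
        raise ValueError("n_best must not exceed n_random")
    rng = np.random.default_rng(seed)
    F_seed = F0
    best_F, best_obj = None, np.inf
    diags = ChemtaxDiagnostics(best_objectives=[], run_objectives=[])
    for _ in range(n_runs):
        candidates = []
        for k in range(n_random):
            Fp = perturb_ratio_matrix(F_seed, magnitude, rng)
            Fo, trace = optimize_ratio_matrix(
                S, Fp, max_iter=max_iter, bound=bound, weighting=weighting
            )
            candidates.append((trace[-1], k, Fo))
        candidates.sort(key=lambda t: (t[0], t[1]))
        if candidates[0][0] < best_obj:
            best_obj, _, best_F = candidates[0]
        # best objective so far; non-increasing across runs by construction
        diags.best_objectives.append(best_obj)
        diags.run_objectives.append([c[0] for c in candidates])
        top = candidates[: n_best]
        mean_vals = np.mean([c[2].to_numpy(float) for c in top], axis=0)
        F_seed = pd.DataFrame(mean_vals, index=F0.index, columns=F0.columns)
    comp, _ = fit_composition(S, best_F, weighting)
    return comp, best_F, diags
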