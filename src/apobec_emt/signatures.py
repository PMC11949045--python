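"""Signature activity estimation over 96-channel catalogs.

Two estimation modes are provided:

* **refitting** — non-negative least squares against a fixed reference
  signature matrix (COSMIC-style, channels x signatures), giving per-sample
  absolute activities and relative contributions;
* **de novo extraction** — multiplicative-update NMF minimizing the
  generalized Kullback-Leibler divergence, with seeded random restarts,
  followed by cosine-similarity matching of the extracted signatures to a
  reference set via an optimal one-to-one assignment.

The "APOBEC fraction" used throughout the cohort analyses is the relative
contribution summed over the SBS2+SBS13 pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment, nnls

from .catalog import CHANNELS_96, MutationCatalog

APOBEC_SIGNATURES = ("SBS2", "SBS13")


@dataclass
class SignatureMatrix:
    """Channel distributions of named signatures (96 x k DataFrame).

    Every column is a probability vector over the 96 channels.
    """

    profiles: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.profiles.index) != list(CHANNELS_96):
            raise ValueError("signature rows must be the 96 channels in standard order")
        arr = self.profiles.to_numpy(dtype=float)
        if (arr < -1e-12).any():
            raise ValueError("signature entries must be non-negative")
        sums = arr.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("every signature column must sum to 1")

    @property
    def names(self) -> list[str]:
        return list(self.profiles.columns)

    def matrix(self) -> np.ndarray:
        return self.profiles.to_numpy(dtype=float)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.profiles[name].to_numpy(dtype=float)

    def subset(self, names) -> "SignatureMatrix":
        return SignatureMatrix(self.profiles[list(names)])


@dataclass
class ExposureResult:
    """Per-sample signature activities from refitting.

    ``absolute`` is in mutation units (samples x signatures); ``relative``
    renormalizes each sample row to sum to 1 (NaN row for an all-zero
    sample). ``reconstruction_residual`` is the per-sample relative L2
    error and ``cosine_to_data`` the cosine between the observed catalog
    and its reconstruction.
    """

    absolute: pd.DataFrame
    relative: pd.DataFrame
    reconstruction_residual: pd.Series
    cosine_to_data: pd.Series

    @property
    def signature_names(self) -> list[str]:
        return list(self.absolute.columns)

    @property
    def samples(self) -> list[str]:
        return list(self.absolute.index)


def cosine_similarity(a, b) -> float:
    """Cosine of the angle between two vectors; raises on a zero vector."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


def fit_exposures(catalog: MutationCatalog, reference: SignatureMatrix) -> ExposureResult:
    """Refit each sample's catalog to the reference set by NNLS.

    Minimizes ||catalog_s - S @ a||_2 subject to a >= 0 independently per
    sample. All-zero samples get zero absolute activities and a NaN
    relative row.
    """
    if len(reference.names) == 0:
        raise ValueError("reference signature matrix is empty")
    S = reference.matrix()
    V = catalog.matrix()
    n = V.shape[1]
    A = np.zeros((n, S.shape[1]))
    resid = np.full(n, np.nan)
    cos = np.full(n, np.nan)
    for j in range(n):
        v = V[:, j]
        norm = np.linalg.norm(v)
        if norm == 0:
            continue
        a, r = nnls(S, v)
        A[j] = a
        resid[j] = r / norm
        recon = S @ a
        cos[j] = cosine_similarity(v, recon) if recon.any() else 0.0
    absolute = pd.DataFrame(A, index=catalog.samples, columns=reference.names)
    totals = absolute.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        relative = absolute.div(totals.where(totals > 0), axis=0)
    return ExposureResult(
        absolute=absolute,
        relative=relative,
        reconstruction_residual=pd.Series(resid, index=catalog.samples),
        cosine_to_data=pd.Series(cos, index=catalog.samples),
    )


def relative_contribution(exposures: ExposureResult, signature_subset) -> pd.Series:
    """Summed relative contribution of a subset of signatures, per sample."""
    subset = list(signature_subset)
    unknown = set(subset) - set(exposures.signature_names)
    if unknown:
        raise KeyError(f"unknown signatures: {sorted(unknown)}")
    return exposures.relative[subset].sum(axis=1, skipna=False)


def apobec_fraction(exposures: ExposureResult, pair=APOBEC_SIGNATURES) -> pd.Series:
    """SBS2+SBS13 relative contribution — the per-sample APOBEC fraction."""
    return relative_contribution(exposures, pair)


@dataclass
class NMFResult:
    """De novo factorization of a catalog into signatures x exposures."""

    rank: int
    signatures: SignatureMatrix
    exposures: pd.DataFrame  # samples x rank, absolute scale
    objective_trace: np.ndarray  # generalized KL per accepted iteration
    restarts_used: int
    best_seed: int
    converged: bool = True
    all_objectives: list = field(default_factory=list)


def _generalized_kl(V: np.ndarray, W: np.ndarray, H: np.ndarray, eps: float) -> float:
    R = W @ H
    mask = V > 0
    term = np.zeros_like(V)
    term[mask] = V[mask] * np.log(V[mask] / np.maximum(R[mask], eps))
    return float(term.sum() - V.sum() + R.sum())


def nmf_extract(
    catalog: MutationCatalog,
    rank: int,
    n_restarts: int = 20,
    max_iter: int = 2000,
    tol: float = 1e-6,
    seed: int = 0,
) -> NMFResult:
    """Extract ``rank`` de novo signatures by KL-divergence NMF.

    Multiplicative updates (Lee-Seung) from random non-negative starts;
    the restart with the lowest final objective is kept. Signature columns
    are renormalized to sum to 1 with the scale folded into the exposures.
    """
    V = catalog.matrix()
    n_samples = V.shape[1]
    if rank < 1 or rank > min(96, n_samples):
        raise ValueError(f"rank must be in [1, {min(96, n_samples)}]")
    if (V < 0).any():
        raise ValueError("catalog counts must be non-negative")
    eps = 1e-12
    scale = V.mean() or 1.0
    best = None
    root = np.random.default_rng(seed)
    restart_seeds = root.integers(0, 2**31 - 1, size=n_restarts)
    objectives = []
    for rseed in restart_seeds:
        rng = np.random.default_rng(rseed)
        W = rng.uniform(0.1, 1.0, size=(96, rank)) * scale
        H = rng.uniform(0.1, 1.0, size=(rank, n_samples))
        trace = [_generalized_kl(V, W, H, eps)]
        converged = False
        for _ in range(max_iter):
            R = np.maximum(W @ H, eps)
            W *= ((V / R) @ H.T) / np.maximum(H.sum(axis=1), eps)
            R = np.maximum(W @ H, eps)
            H *= (W.T @ (V / R)) / np.maximum(W.sum(axis=0), eps)[:, None]
            obj = _generalized_kl(V, W, H, eps)
            trace.append(obj)
            prev = trace[-2]
            if prev - obj <= tol * max(abs(prev), 1.0):
                converged = True
                break
        objectives.append(trace[-1])
        if best is None or trace[-1] < best[0]:
            best = (trace[-1], W.copy(), H.copy(), np.array(trace), int(rseed), converged)
    _, W, H, trace, best_seed, converged = best
    if not converged:
        warnings.warn("NMF did not converge within max_iter on the best restart")
    col = W.sum(axis=0)
    W = W / np.maximum(col, eps)
    H = H * col[:, None]
    names = [f"denovo_{i + 1}" for i in range(rank)]
    sig = SignatureMatrix(pd.DataFrame(W, index=list(CHANNELS_96), columns=names))
    expo = pd.DataFrame(H.T, index=catalog.samples, columns=names)
    return NMFResult(
        rank=rank,
        signatures=sig,
        exposures=expo,
        objective_trace=trace,
        restarts_used=n_restarts,
        best_seed=best_seed,
        converged=converged,
        all_objectives=objectives,
    )


def match_signatures(
    denovo: SignatureMatrix,
    reference: SignatureMatrix,
    reporting_floor: float = 0.75,
) -> list[tuple[str, str, float, bool]]:
    """Optimal one-to-one assignment of de novo to reference signatures.

    Maximizes the total cosine similarity (rectangular assignment problem).
    Returns ``(denovo_name, reference_name, cosine, assigned)`` tuples;
    pairs with cosine below ``reporting_floor`` are flagged unassigned.
    """
    D, R = denovo.matrix(), reference.matrix()
    sim = np.zeros((D.shape[1], R.shape[1]))
    for i in range(D.shape[1]):
        for j in range(R.shape[1]):
            sim[i, j] = cosine_similarity(D[:, i], R[:, j])
    rows, cols = linear_sum_assignment(-sim)
    out = []
    for i, j in zip(rows, cols):
        c = float(sim[i, j])
        out.append((denovo.names[i], reference.names[j], c, c >= reporting_floor))
    return out


def prune_reference(
    catalog: MutationCatalog,
    reference: SignatureMatrix,
    min_cosine_drop: float = 0.01,
) -> SignatureMatrix:
    """Backward elimination of reference signatures that do not help.

    Repeatedly drops the signature whose removal degrades the mean
    cosine-to-data by less than ``min_cosine_drop``. Guards against
    the overfitting that refitting to a large reference set invites.
    """
    names = list(reference.names)
    current = np.nanmean(fit_exposures(catalog, reference).cosine_to_data)
    while len(names) > 1:
        best_drop, best_cos = None, -np.inf
        for name in names:
            trial = [n for n in names if n != name]
            cos = np.nanmean(
                fit_exposures(catalog, reference.subset(trial)).cosine_to_data
            )
            if cos > best_cos:
                best_drop, best_cos = name, cos
        if current - best_cos < min_cosine_drop:
            names.remove(best_drop)
            current = best_cos
        else:
            break
    return reference.subset(names)


def grid_search_relative(
    counts: np.ndarray, reference: SignatureMatrix, step: float = 1e-3
) -> np.ndarray:
    """Exhaustive simplex grid search for the relative contributions that
    minimize the squared reconstruction error of a normalized catalog.

    For every grid point on the relative-weight simplex the overall
    activity scale is profiled out analytically (the non-negative scale
    minimizing the squared error is closed-form), so the enumeration
    searches exactly the same objective NNLS optimizes. Independent
    oracle for :func:`fit_exposures`; tractable for <= 3 signatures only.
    """
    S = reference.matrix()
    k = S.shape[1]
    if k > 3:
        raise ValueError("grid search oracle supports at most 3 signatures")
    v = np.asarray(counts, dtype=float)
    v = v / v.sum()
    if k == 1:
        return np.array([1.0])
    ticks = np.round(np.arange(0, 1 + step / 2, step), 9)
    if k == 2:
        grid = np.column_stack([ticks, 1 - ticks])
    else:
        a, b = np.meshgrid(ticks, ticks, indexing="ij")
        keep = (a + b) <= 1 + 1e-12
        grid = np.column_stack([a[keep], b[keep], 1 - a[keep] - b[keep]])
    best_w, best_resid = None, np.inf
    vv = float(v @ v)
    for start in range(0, len(grid), 50000):  # chunked to bound memory
        block = grid[start : start + 50000]
        U = block @ S.T  # candidate reconstruction directions
        dots = np.maximum(U @ v, 0.0)
        norms = np.einsum("ij,ij->i", U, U)
        # residual after the optimal non-negative scaling of each direction
        resid = vv - dots**2 / np.maximum(norms, 1e-300)
        i = int(np.argmin(resid))
        if resid[i] < best_resid:
            best_w, best_resid = block[i], float(resid[i])
    return best_w
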