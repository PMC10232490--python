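"""Mutational signature analysis.

The workflow is the standard one for somatic substitution signatures:
build a samples x 96 trinucleotide-context catalogue, factorize it with
non-negative matrix factorization (NMF), match the factors to a
reference catalogue by cosine similarity, and estimate per-sample
exposures by constrained least squares (a quadratic programme on the
probability simplex). To avoid over-fitting, exposures below 10% of a
sample's mutations are pruned and the mutations reassigned to the
remaining signatures by refitting, iterated smallest-first until every
retained exposure clears the threshold or a single signature remains.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.decomposition import NMF

from .constants import SNV_CHANNELS_96
from .types import SignatureSet, SnvRecord

logger = logging.getLogger(__name__)

__all__ = [
    "build_snv_catalogue",
    "extract_signatures_nmf",
    "match_signatures_cosine",
    "refit_exposures",
    "refit_exposure_matrix",
    "prune_and_reassign",
]


def build_snv_catalogue(
    records: Sequence[SnvRecord], samples: Sequence[str]
) -> pd.DataFrame:
    """Count SNVs into the 96-channel catalogue (samples x channels).

    Samples with no records get zero rows; a record whose sample is not
    in ``samples`` raises.
    """
    samples = list(samples)
    index = {s: i for i, s in enumerate(samples)}
    counts = np.zeros((len(samples), 96), dtype=np.int64)
    channel_index = {c: j for j, c in enumerate(SNV_CHANNELS_96)}
    for r in records:
        if r.sample_id not in index:
            raise KeyError(f"unknown sample {r.sample_id!r}")
        counts[index[r.sample_id], channel_index[r.channel]] += 1
    return pd.DataFrame(counts, index=samples, columns=list(SNV_CHANNELS_96))


def extract_signatures_nmf(
    catalogue: pd.DataFrame,
    k: int,
    n_restarts: int = 50,
    max_iter: int = 10_000,
    tol: float = 1e-6,
    seed: int = 0,
) -> tuple[SignatureSet, pd.DataFrame, float]:
    """De novo signature extraction by Frobenius NMF (multiplicative updates).

    Runs ``n_restarts`` random initialisations and keeps the best fit by
    reconstruction error. Factor rows are normalized to probability
    vectors, with the exposures rescaled accordingly and reported as
    per-sample proportions.

    Returns ``(signatures, exposures, relative_reconstruction_error)``.
    """
    X = catalogue.to_numpy(dtype=float)
    if X.sum() == 0:
        raise ValueError("all-zero catalogue")
    if k > min(X.shape):
        logger.warning("k=%d exceeds data rank support %d; proceeding", k, min(X.shape))
    rng = np.random.default_rng(seed)
    best: Optional[tuple[float, np.ndarray, np.ndarray]] = None
    for _ in range(max(n_restarts, 1)):
        model = NMF(
            n_components=k,
            init="random",
            solver="mu",
            beta_loss="frobenius",
            max_iter=max_iter,
            tol=tol,
            random_state=int(rng.integers(2**31)),
        )
        W = model.fit_transform(X)
        H = model.components_
        err = float(np.linalg.norm(X - W @ H))
        if best is None or err < best[0]:
            best = (err, W, H)
    err, W, H = best
    row_sums = H.sum(axis=1)
    row_sums[row_sums == 0] = 1.0
    profiles = H / row_sums[:, None]
    loads = W * row_sums[None, :]  # mutation loads per signature
    totals = loads.sum(axis=1)
    totals[totals == 0] = 1.0
    exposures = loads / totals[:, None]
    names = [f"E{i + 1}" for i in range(k)]
    sigset = SignatureSet(
        pd.DataFrame(profiles, index=names, columns=catalogue.columns),
        provenance="extracted",
    )
    expo = pd.DataFrame(exposures, index=catalogue.index, columns=names)
    rel_err = err / max(np.linalg.norm(X), 1e-300)
    return sigset, expo, rel_err


def match_signatures_cosine(
    extracted: SignatureSet,
    reference: SignatureSet,
    like_threshold: Optional[float] = None,
) -> pd.DataFrame:
    """Best-cosine match of each extracted signature to the reference set.

    Ties are broken by reference order. When ``like_threshold`` is set,
    matches with cosine below it are labelled ``"<name>-like"`` in the
    ``label`` column (mirroring the convention of naming divergent
    rearrangement signatures e.g. RS3-like).
    """
    if list(extracted.channels) != list(reference.channels):
        raise ValueError("channel order mismatch between signature sets")
    E = extracted.profiles.to_numpy(dtype=float)
    R = reference.profiles.to_numpy(dtype=float)
    En = E / np.maximum(np.linalg.norm(E, axis=1, keepdims=True), 1e-300)
    Rn = R / np.maximum(np.linalg.norm(R, axis=1, keepdims=True), 1e-300)
    sim = np.clip(En @ Rn.T, 0.0, 1.0)
    rows = []
    for i, name in enumerate(extracted.names):
        j = int(np.argmax(sim[i]))  # argmax takes the first max: reference order
        ref_name = reference.names[j]
        cos = float(sim[i, j])
        label = ref_name
        if like_threshold is not None and cos < like_threshold:
            label = f"{ref_name}-like"
        tie = int((sim[i] == sim[i, j]).sum()) > 1
        rows.append((name, ref_name, cos, label, tie))
    return pd.DataFrame(
        rows, columns=["extracted", "reference", "cosine", "label", "tie"]
    )


def refit_exposures(
    counts: Sequence[float], signatures: SignatureSet
) -> tuple[np.ndarray, float]:
    """Quadratic-programming exposure refit for one catalogue row.

    Minimizes ``|| m/||m||_1 - S^T e ||_2^2`` subject to ``e >= 0`` and
    ``sum(e) = 1`` (SLSQP with analytic gradient). Returns the exposure
    vector and the objective value; a zero-count row yields the zero
    vector with objective NaN.
    """
    m = np.asarray(counts, dtype=float)
    S = signatures.profiles.to_numpy(dtype=float)  # k x channels
    k = S.shape[0]
    if k < 1:
        raise ValueError("need at least one signature")
    total = m.sum()
    if total == 0:
        return np.zeros(k), float("nan")
    m = m / total
    G = S @ S.T  # k x k
    b = S @ m

    def objective(e):
        return float(e @ G @ e - 2 * b @ e + m @ m)

    if k <= 12:
        e = _simplex_qp_exact(G, b)
    else:
        e = _simplex_qp_slsqp(G, b, k)
    return e, objective(e)


def _simplex_qp_exact(G: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Exact simplex-constrained least squares by support enumeration.

    For every candidate support the equality-constrained KKT system is
    solved; among supports whose solution is primal feasible the best
    objective wins. Exponential in k, so reserved for small k.
    """
    from itertools import combinations

    k = len(b)
    best_e, best_obj = None, np.inf
    idx = np.arange(k)
    for size in range(1, k + 1):
        for support in combinations(idx, size):
            s = np.array(support)
            A = np.zeros((size + 1, size + 1))
            A[:size, :size] = 2 * G[np.ix_(s, s)]
            A[:size, size] = 1.0
            A[size, :size] = 1.0
            rhs = np.concatenate([2 * b[s], [1.0]])
            try:
                sol = np.linalg.solve(A, rhs)
            except np.linalg.LinAlgError:
                continue
            e_s = sol[:size]
            if (e_s < -1e-12).any():
                continue
            e = np.zeros(k)
            e[s] = np.clip(e_s, 0.0, None)
            e /= e.sum()
            obj = float(e @ G @ e - 2 * b @ e)
            if obj < best_obj - 1e-15:
                best_e, best_obj = e, obj
    return best_e


def _simplex_qp_slsqp(G: np.ndarray, b: np.ndarray, k: int) -> np.ndarray:
    res = minimize(
        lambda e: float(e @ G @ e - 2 * b @ e),
        np.full(k, 1.0 / k),
        jac=lambda e: 2 * (G @ e - b),
        method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda e: e.sum() - 1.0,
                      "jac": lambda e: np.ones_like(e)}],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    e = np.clip(res.x, 0.0, None)
    return e / e.sum()


def refit_exposure_matrix(
    catalogue: pd.DataFrame, signatures: SignatureSet
) -> pd.DataFrame:
    """Refit every catalogue row; returns samples x signatures proportions."""
    rows = [refit_exposures(catalogue.loc[s].to_numpy(), signatures)[0]
            for s in catalogue.index]
    return pd.DataFrame(rows, index=catalogue.index, columns=signatures.names)


def prune_and_reassign(
    exposures: pd.DataFrame,
    catalogue: pd.DataFrame,
    signatures: SignatureSet,
    threshold: float = 0.10,
) -> pd.DataFrame:
    """Drop sub-threshold exposures and reassign their mutations.

    Per sample, iteratively remove the smallest exposure below
    ``threshold`` (ties by signature order) and refit on the remaining
    signatures, until every retained exposure is at least ``threshold``
    or a single signature remains. Rows stay on the simplex; omitted
    signatures get exposure 0.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    names = list(signatures.names)
    out = pd.DataFrame(0.0, index=exposures.index, columns=names)
    profiles = signatures.profiles
    for sample in exposures.index:
        active = list(names)
        expo = exposures.loc[sample, active].to_numpy(dtype=float)
        counts = catalogue.loc[sample].to_numpy(dtype=float)
        if counts.sum() == 0:
            continue
        while len(active) > 1:
            below = np.flatnonzero(expo < threshold)
            if below.size == 0:
                break
            drop = below[np.argmin(expo[below])]  # smallest first; argmin ties -> lowest index
            active.pop(int(drop))
            sub = SignatureSet(profiles.loc[active], provenance=signatures.provenance)
            expo, _ = refit_exposures(counts, sub)
        out.loc[sample, active] = expo
    return out
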