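"""Nonnegative matrix factorization by multiplicative updates.

Classic Frobenius-norm NMF (Lee-Seung multiplicative updates), run over a
range of ranks to produce a multilevel family of factorizations: low ranks
yield broad subject groups sharing few features, high ranks yield specific
groups sharing many features. Multiplicative updates guarantee a
monotonically nonincreasing objective, which the tests assert on every run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_EPS = 1e-12


@dataclass
class NMFModel:
    """A fitted factorization V ~ W H with diagnostics."""

    W: np.ndarray  # (m, k) subject loadings, >= 0
    H: np.ndarray  # (k, n) feature loadings, >= 0
    rank: int
    objective_trace: np.ndarray  # Frobenius error per iteration
    seed: int
    iterations: int
    converged: bool

    @property
    def objective(self) -> float:
        return float(self.objective_trace[-1])


def _init_factors(
    V: np.ndarray, k: int, init_mode: str, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    m, n = V.shape
    if init_mode == "random-uniform":
        scale = np.sqrt(V.mean() / k) + _EPS
        return rng.uniform(0, 1, (m, k)) * scale, rng.uniform(0, 1, (k, n)) * scale
    if init_mode == "nndsvd":
        # nonnegative double SVD: positive parts of leading singular vectors
        U, s, Vt = np.linalg.svd(V, full_matrices=False)
        W = np.zeros((m, k))
        H = np.zeros((k, n))
        W[:, 0] = np.sqrt(s[0]) * np.abs(U[:, 0])
        H[0] = np.sqrt(s[0]) * np.abs(Vt[0])
        for j in range(1, k):
            u, v = U[:, j], Vt[j]
            up, un = np.maximum(u, 0), np.maximum(-u, 0)
            vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
            n_up, n_vp = np.linalg.norm(up), np.linalg.norm(vp)
            n_un, n_vn = np.linalg.norm(un), np.linalg.norm(vn)
            if n_up * n_vp >= n_un * n_vn:
                sigma = n_up * n_vp
                if sigma > 0:
                    W[:, j] = np.sqrt(s[j] * sigma) * up / n_up
                    H[j] = np.sqrt(s[j] * sigma) * vp / n_vp
            else:
                sigma = n_un * n_vn
                if sigma > 0:
                    W[:, j] = np.sqrt(s[j] * sigma) * un / n_un
                    H[j] = np.sqrt(s[j] * sigma) * vn / n_vn
        # small positive fill so multiplicative updates cannot lock zeros at init
        mean = V.mean()
        W[W == 0] = mean / 100
        H[H == 0] = mean / 100
        return W, H
    raise ValueError(f"unknown init_mode: {init_mode!r}")


def factorize(
    V: np.ndarray,
    k: int,
    init_mode: str = "random-uniform",
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> NMFModel:
    """Fit rank-``k`` NMF to nonnegative ``V`` by multiplicative updates.

    Stops when the relative decrease of the Frobenius error falls below
    ``tol`` or after ``max_iter`` iterations. Deterministic for a fixed
    seed and init mode.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise ValueError("V must be a matrix")
    if (V < 0).any():
        raise ValueError("V must be nonnegative")
    if not V.any():
        raise ValueError("V is identically zero; nothing to factorize")
    m, n = V.shape
    if not 1 <= k < min(m, n):
        raise ValueError(f"rank k={k} out of range [1, {min(m, n) - 1}]")

    rng = np.random.default_rng(seed)
    W, H = _init_factors(V, k, init_mode, rng)

    trace = [np.linalg.norm(V - W @ H)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # H <- H * (W^T V) / (W^T W H)
        H *= (W.T @ V) / np.maximum(W.T @ W @ H, _EPS)
        # W <- W * (V H^T) / (W H H^T)
        W *= (V @ H.T) / np.maximum(W @ (H @ H.T), _EPS)
        err = np.linalg.norm(V - W @ H)
        trace.append(err)
        if abs(trace[-2] - err) <= tol * max(trace[0], _EPS):
            converged = True
            break
    return NMFModel(
        W=W, H=H, rank=k, objective_trace=np.asarray(trace),
        seed=seed, iterations=it, converged=converged,
    )


def multilevel_factorize(
    V: np.ndarray,
    k_min: int = 2,
    k_max: int = 10,
    restarts: int = 5,
    seed: int = 0,
    init_mode: str = "random-uniform",
    tol: float = 1e-6,
    max_iter: int = 500,
) -> list[NMFModel]:
    """Fit NMF for every rank in [k_min, k_max], keeping the best of
    ``restarts`` random restarts (lowest final objective) per rank.

    Restart seeds are derived from the master seed by fixed offsets, so a
    fixed master seed reproduces the whole family bitwise.
    """
    if k_min < 2:
        raise ValueError("k_min must be >= 2")
    m, n = np.asarray(V).shape
    if k_max > min(m, n) - 1:
        raise ValueError(f"k_max={k_max} exceeds min(m, n) - 1 = {min(m, n) - 1}")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    family = []
    for k in range(k_min, k_max + 1):
        best: NMFModel | None = None
        for r in range(restarts):
            sub_seed = (seed * 1000 + k * 37 + r) % (2**31)
            model = factorize(
                V, k, init_mode=init_mode, seed=sub_seed, tol=tol, max_iter=max_iter
            )
            if best is None or model.objective < best.objective:
                best = model
        family.append(best)
    return family
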