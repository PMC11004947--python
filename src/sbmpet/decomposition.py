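"""PCA dimension reduction and Infomax spatial ICA (source-based morphometry core).

The demeaned subjects x voxels matrix ``X`` is reduced by SVD to its top-K
row-space basis, whitened across the voxel dimension, and unmixed by the
Infomax algorithm (natural-gradient entropy maximization through a logistic
nonlinearity). The result is a decomposition

    X  ~=  mixing (N x K)  @  sources (K x V)

where each source row is a spatial pattern and each mixing column holds the
per-subject loading weights of that pattern. Row permutation and sign are
intrinsically ambiguous; :func:`orient_sources` fixes a canonical sign
(peak-positive) and :func:`match_sources` aligns an estimate with a known
ground truth for recovery experiments.

Because the rows of ``X`` are mean-free, the right-singular vectors are
exactly zero-mean over voxels, so the whitened PCA images have identity
covariance by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit


@dataclass
class PcaReduction:
    """Top-K principal subspace of the demeaned subject matrix.

    ``component_images`` (K x V) are orthonormal right-singular vectors;
    ``projection`` (N x K) are subject coordinates such that
    ``projection @ component_images`` is the best rank-K approximation.
    """

    n_components: int
    component_images: np.ndarray
    projection: np.ndarray
    singular_values: np.ndarray
    explained_variance_fraction: np.ndarray
    discarded_energy: float  # sum of squared discarded singular values

    @property
    def n_voxels(self) -> int:
        return self.component_images.shape[1]

    def whitened_images(self) -> np.ndarray:
        """K x V images with exactly unit variance and zero cross-covariance."""
        return self.component_images * np.sqrt(self.n_voxels)

    def truncation_rmse(self, n_subjects: int) -> float:
        """RMS of the rank-K residual over the full N x V matrix."""
        return float(np.sqrt(self.discarded_energy / (n_subjects * self.n_voxels)))


@dataclass
class SbmDecomposition:
    """ICA unmixing of the PCA-reduced data: loading weights + spatial sources."""

    mixing: np.ndarray  # N x K subject loading weights
    sources: np.ndarray  # K x V spatial source values
    unmixing: np.ndarray  # K x K rotation applied to the whitened PCA images
    converged: bool
    n_iterations: int
    seed: int
    reconstruction_rmse: float
    pca: PcaReduction

    @property
    def n_components(self) -> int:
        return self.sources.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.mixing.shape[0]


def pca_reduce(m, n_components: int) -> PcaReduction:
    """Reduce a row-demeaned SubjectMatrix to its top-K principal subspace.

    K must satisfy ``1 <= K <= min(N-1, V)``: row demeaning removes one
    degree of freedom, so the matrix rank is at most N-1.
    """
    if not m.demeaned:
        raise ValueError("pca_reduce requires a row-demeaned matrix")
    n, v = m.data.shape
    k_max = min(n - 1, v)
    if not 1 <= n_components <= k_max:
        raise ValueError(
            f"n_components must be in [1, {k_max}] for a row-demeaned "
            f"{n}x{v} matrix, got {n_components}"
        )
    total_energy = float(np.sum(m.data**2))
    if total_energy == 0.0:
        raise ValueError("zero-variance data: nothing to decompose")
    u, s, vt = np.linalg.svd(m.data, full_matrices=False)
    k = n_components
    return PcaReduction(
        n_components=k,
        component_images=vt[:k],
        projection=u[:, :k] * s[:k],
        singular_values=s[:k].copy(),
        explained_variance_fraction=s[:k] ** 2 / total_energy,
        discarded_energy=float(np.sum(s[k:] ** 2)),
    )


def _default_learning_rate(k: int) -> float:
    return 0.015 / np.log(k) if k > 1 else 0.015


def infomax_ica(
    pca: PcaReduction,
    seed: int,
    learning_rate: float | None = None,
    max_iterations: int = 512,
    tolerance: float = 1e-6,
    batch_size: int | None = None,
    extended: bool = False,
    demeaned_data: np.ndarray | None = None,
) -> SbmDecomposition:
    """Unmix whitened PCA images with natural-gradient Infomax ICA.

    Training iterates full passes over the voxels in seeded random-permutation
    mini-batches, updating the K x K weight matrix ``W`` by the natural
    gradient ``dW = lr * (I + (1 - 2 g(U)) U^T / B) W`` with the logistic
    nonlinearity ``g(u) = 1/(1+exp(-u))`` (batch size B). The learning rate is
    annealed by 0.9 whenever a pass's weight change fails to shrink (a
    divergence/oscillation guard), and training stops when the per-pass
    Frobenius change drops below ``tolerance``. With ``extended=True`` the
    sign of each component's nonlinearity follows a running kurtosis estimate,
    accommodating sub-Gaussian sources.

    ``demeaned_data`` (N x V) is used to recover the mixing matrix by
    least-squares projection onto the sources; when omitted, the PCA
    projection chain is used (identical in exact arithmetic).
    """
    k = pca.n_components
    if k < 1:
        raise ValueError("need at least one component")
    z = pca.whitened_images()
    v = z.shape[1]

    if k == 1:
        sources = pca.component_images.copy()
        mixing = pca.projection.copy()
        d = SbmDecomposition(
            mixing=mixing,
            sources=sources,
            unmixing=np.eye(1),
            converged=True,
            n_iterations=0,
            seed=seed,
            reconstruction_rmse=pca.truncation_rmse(mixing.shape[0]),
            pca=pca,
        )
        return d

    rng = np.random.default_rng(seed)
    lr = _default_learning_rate(k) if learning_rate is None else float(learning_rate)
    if lr <= 0:
        raise ValueError("learning_rate must be positive")
    b = batch_size if batch_size is not None else int(min(v, max(64, 8 * k)))

    w = np.eye(k)
    eye = np.eye(k)
    signs = np.ones(k)  # +1 super-Gaussian, -1 sub-Gaussian (extended only)
    prev_delta = np.inf
    converged = False
    n_iter = 0

    for n_iter in range(1, max_iterations + 1):
        w_prev = w.copy()
        perm = rng.permutation(v)
        for start in range(0, v, b):
            idx = perm[start : start + b]
            u = w @ z[:, idx]
            if extended:
                y = np.tanh(u)
                grad = eye - (signs[:, None] * y) @ u.T / idx.size - u @ u.T / idx.size
            else:
                y = expit(u)
                grad = eye + (1.0 - 2.0 * y) @ u.T / idx.size
            w = w + lr * grad @ w
            if not np.all(np.isfinite(w)) or np.max(np.abs(w)) > 1e8:
                # weight blowup: restart from identity with a halved rate
                w = np.eye(k)
                lr *= 0.5
                prev_delta = np.inf
                break
        else:
            if extended:
                u_full = w @ z
                m2 = np.mean(u_full**2, axis=1)
                m4 = np.mean(u_full**4, axis=1)
                signs = np.sign(m4 / m2**2 - 3.0)
                signs[signs == 0] = 1.0
            delta = float(np.linalg.norm(w - w_prev))
            if delta < tolerance:
                converged = True
                break
            if delta >= prev_delta:
                lr *= 0.9
            prev_delta = delta

    sources = w @ z
    if demeaned_data is None:
        # mixing through the PCA chain: X ~ P Vt = (P / sqrt(V)) Z = (P/sqrt(V)) W^-1 S
        mixing = (pca.projection / np.sqrt(v)) @ np.linalg.inv(w)
        n_subjects = pca.projection.shape[0]
        recon_rmse = pca.truncation_rmse(n_subjects)
    else:
        mixing, *_ = np.linalg.lstsq(sources.T, demeaned_data.T, rcond=None)
        mixing = mixing.T
        resid = demeaned_data - mixing @ sources
        recon_rmse = float(np.sqrt(np.mean(resid**2)))
        n_subjects = demeaned_data.shape[0]

    if np.any(sources.std(axis=1) == 0):
        raise ValueError("ICA produced a zero-variance source (degenerate input)")

    return SbmDecomposition(
        mixing=mixing,
        sources=sources,
        unmixing=w,
        converged=converged,
        n_iterations=n_iter,
        seed=seed,
        reconstruction_rmse=recon_rmse,
        pca=pca,
    )


def orient_sources(d: SbmDecomposition) -> SbmDecomposition:
    """Fix the sign ambiguity: flip each source so its extreme voxel is positive.

    The mixing column is negated together with the source row, so the product
    ``mixing @ sources`` is unchanged.
    """
    sources = d.sources.copy()
    mixing = d.mixing.copy()
    for k in range(sources.shape[0]):
        peak = np.argmax(np.abs(sources[k]))
        if sources[k, peak] < 0:
            sources[k] = -sources[k]
            mixing[:, k] = -mixing[:, k]
    return replace(d, sources=sources, mixing=mixing)


@dataclass
class SourceMatch:
    """One matched (true source, estimated component) pair."""

    true_index: int
    est_index: int
    spatial_r: float  # signed Pearson correlation of source maps
    loading_r: float  # signed correlation of loading weights
    sign: int  # sign of the spatial correlation


def match_sources(
    estimated: SbmDecomposition,
    truth_sources: np.ndarray,
    truth_loadings: np.ndarray | None = None,
) -> list[SourceMatch]:
    """Greedily pair true sources with estimated components by |spatial r|.

    Each true source is matched to a distinct estimated component, in
    descending order of absolute spatial Pearson correlation. Loading
    correlations are reported on the matched pairs (signed consistently with
    the spatial match).
    """
    truth_sources = np.asarray(truth_sources, dtype=np.float64)
    if truth_sources.ndim != 2 or truth_sources.shape[1] != estimated.sources.shape[1]:
        raise ValueError(
            f"truth sources shape {truth_sources.shape} incompatible with "
            f"estimated {estimated.sources.shape}"
        )
    k_true = truth_sources.shape[0]
    k_est = estimated.sources.shape[0]
    if k_true > k_est:
        raise ValueError(f"more true sources ({k_true}) than estimated ({k_est})")
    if truth_loadings is not None:
        truth_loadings = np.asarray(truth_loadings, dtype=np.float64)
        if truth_loadings.shape != (estimated.mixing.shape[0], k_true):
            raise ValueError("truth loadings shape mismatch")

    def _corr(a: np.ndarray, b: np.ndarray) -> float:
        a = a - a.mean()
        b = b - b.mean()
        denom = np.linalg.norm(a) * np.linalg.norm(b)
        return float(a @ b / denom) if denom > 0 else 0.0

    corr = np.array(
        [[_corr(truth_sources[i], estimated.sources[j]) for j in range(k_est)] for i in range(k_true)]
    )
    matches: list[SourceMatch] = []
    used_true: set[int] = set()
    used_est: set[int] = set()
    abs_corr = np.abs(corr)
    for _ in range(k_true):
        masked = abs_corr.copy()
        for i in used_true:
            masked[i, :] = -1
        for j in used_est:
            masked[:, j] = -1
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        used_true.add(int(i))
        used_est.add(int(j))
        r = corr[i, j]
        loading_r = np.nan
        if truth_loadings is not None:
            loading_r = _corr(truth_loadings[:, i], estimated.mixing[:, j])
        matches.append(
            SourceMatch(
                true_index=int(i),
                est_index=int(j),
                spatial_r=r,
                loading_r=loading_r,
                sign=int(np.sign(r)) if r != 0 else 1,
            )
        )
    matches.sort(key=lambda m: m.true_index)
    return matches
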