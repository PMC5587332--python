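"""Gaussian-process latent variable model over backbone coordinates.

The model places the N input conformations at latent coordinates
X in R^{N x L} (L = 2 by default) and treats each of the D coordinate
columns of the centred data matrix as an independent draw from a GP with a
shared kernel.  With the composite RBF + bias kernel

    k(x_s, x_t) = theta0 * exp(-1/2 * sum_l theta_l * (x_sl - x_tl)^2) + theta3

the marginal likelihood of the data columns times a standard-normal prior
on the latents gives the negative log posterior

    L(X, theta, sigma2) = DN/2 log 2pi + D/2 log|K + sigma2 I|
                          + 1/2 Tr((K + sigma2 I)^{-1} Y Y^T)
                          + 1/2 sum_n x_n^T x_n

which is minimised jointly over X, log-kernel parameters and log noise
variance with L-BFGS and analytic gradients.  With a linear kernel the
model reduces to probabilistic PCA: the optimal latent subspace is the span
of the top-L principal components.

New backbones are reconstructed from an arbitrary latent point x* through
the GP predictive mean,

    E[y*] = mean(Y) + k_{x*,X} (K + sigma2 I)^{-1} (Y - mean(Y)),

with a predictive variance shared across coordinate columns.  Because the
kernel is smooth, straight-line moves in latent space map to concerted
multi-atom Cartesian movements interpolating the input structures.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize

from .structures import BackboneStructure, DataMatrix

KernelName = Literal["rbf", "linear"]

_JITTER = 1e-8
_FORMAT_VERSION = 1


@dataclass
class KernelParams:
    """Composite kernel hyperparameters.

    theta0   RBF (or linear) amplitude, > 0
    theta_l  per-latent-dimension inverse-squared length-scale weights, > 0
             (RBF kernel only; empty for the linear kernel)
    theta3   bias (constant) amplitude, >= 0
    """

    theta0: float
    theta_l: np.ndarray
    theta3: float

    def __post_init__(self) -> None:
        self.theta_l = np.atleast_1d(np.asarray(self.theta_l, dtype=float))
        if self.theta0 <= 0:
            raise ValueError("theta0 must be strictly positive")
        if np.any(self.theta_l <= 0):
            raise ValueError("theta_l weights must be strictly positive")
        if self.theta3 < 0:
            raise ValueError("theta3 must be non-negative")


def kernel_matrix(A: np.ndarray, B: np.ndarray, params: KernelParams,
                  kernel: KernelName = "rbf") -> np.ndarray:
    """Kernel Gram matrix between two point sets (m x L and n x L)."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"latent dimension mismatch: {A.shape[1]} vs {B.shape[1]}")
    if kernel == "rbf":
        if params.theta_l.shape[0] != A.shape[1]:
            raise ValueError("theta_l length must equal the latent dimension")
        diff = A[:, None, :] - B[None, :, :]
        d2 = np.einsum("mnl,l->mn", diff ** 2, params.theta_l)
        return params.theta0 * np.exp(-0.5 * d2) + params.theta3
    if kernel == "linear":
        return params.theta0 * (A @ B.T) + params.theta3
    raise ValueError(f"unknown kernel {kernel!r}")


def kernel_diag(A: np.ndarray, params: KernelParams,
                kernel: KernelName = "rbf") -> np.ndarray:
    A = np.atleast_2d(np.asarray(A, dtype=float))
    if kernel == "rbf":
        return np.full(A.shape[0], params.theta0 + params.theta3)
    return params.theta0 * np.einsum("ij,ij->i", A, A) + params.theta3


def _chol_with_jitter(M: np.ndarray) -> tuple[np.ndarray, float]:
    """Lower Cholesky factor, escalating a diagonal jitter if needed."""
    jitter = 0.0
    scale = float(np.mean(np.diag(M)))
    for attempt in range(6):
        try:
            L = cholesky(M + jitter * np.eye(M.shape[0]), lower=True)
            return L, jitter
        except np.linalg.LinAlgError:
            jitter = _JITTER * scale * (10.0 ** attempt) if jitter == 0 else jitter * 10
    raise np.linalg.LinAlgError(
        "covariance K + sigma2*I is not positive definite even with jitter up "
        "to 1e-3; increase the noise variance or rescale the data"
    )


def neg_log_posterior(X: np.ndarray, Y_centered: np.ndarray,
                      params: KernelParams, noise_variance: float,
                      kernel: KernelName = "rbf") -> float:
    """Negative log posterior of the latent variable model (see module doc)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Yc = np.asarray(Y_centered, dtype=float)
    N, D = Yc.shape
    K = kernel_matrix(X, X, params, kernel)
    M = K + noise_variance * np.eye(N)
    L, _ = _chol_with_jitter(M)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    alpha = cho_solve((L, True), Yc)
    return (
        0.5 * D * N * np.log(2.0 * np.pi)
        + 0.5 * D * logdet
        + 0.5 * float(np.sum(alpha * Yc))
        + 0.5 * float(np.sum(X ** 2))
    )


def _objective_and_grad(vec: np.ndarray, Yc: np.ndarray, N: int, L_dim: int,
                        kernel: KernelName) -> tuple[float, np.ndarray]:
    """Objective and analytic gradient in the packed log-parameterisation.

    Packing: [X.ravel(), log theta0, (log theta_l)*L (rbf only),
              log theta3, log sigma2].
    """
    X = vec[: N * L_dim].reshape(N, L_dim)
    pos = N * L_dim
    log_theta0 = vec[pos]; pos += 1
    if kernel == "rbf":
        log_theta_l = vec[pos: pos + L_dim]; pos += L_dim
        theta_l = np.exp(log_theta_l)
    else:
        theta_l = np.ones(L_dim)
    log_theta3 = vec[pos]; pos += 1
    log_sigma2 = vec[pos]
    theta0, theta3, sigma2 = np.exp(log_theta0), np.exp(log_theta3), np.exp(log_sigma2)

    D = Yc.shape[1]
    if kernel == "rbf":
        diff = X[:, None, :] - X[None, :, :]
        d2 = np.einsum("mnl,l->mn", diff ** 2, theta_l)
        R = theta0 * np.exp(-0.5 * d2)      # RBF block
        K = R + theta3
    else:
        G = X @ X.T
        K = theta0 * G + theta3
    M = K + sigma2 * np.eye(N)
    Lc, _ = _chol_with_jitter(M)
    logdet = 2.0 * float(np.sum(np.log(np.diag(Lc))))
    alpha = cho_solve((Lc, True), Yc)       # M^{-1} Yc, N x D

    f = (0.5 * D * N * np.log(2.0 * np.pi) + 0.5 * D * logdet
         + 0.5 * float(np.sum(alpha * Yc)) + 0.5 * float(np.sum(X ** 2)))

    # dL/dM = W = (D/2) M^{-1} - (1/2) M^{-1} Y Y^T M^{-1}  (symmetric)
    Minv = cho_solve((Lc, True), np.eye(N))
    W = 0.5 * (D * Minv - alpha @ alpha.T)

    grad = np.empty_like(vec)
    if kernel == "rbf":
        WR = W * R
        gX = np.empty_like(X)
        for l in range(L_dim):
            xl = X[:, l]
            # sum_t WR_nt * (x_nl - x_tl), doubled because (n,t) and (t,n)
            gX[:, l] = -2.0 * theta_l[l] * (WR.sum(axis=1) * xl - WR @ xl)
        gX += X  # latent prior
        grad[: N * L_dim] = gX.ravel()
        pos = N * L_dim
        grad[pos] = float(np.sum(WR)); pos += 1
        for l in range(L_dim):
            d2_l = (X[:, l, None] - X[None, :, l]) ** 2
            grad[pos + l] = -0.5 * theta_l[l] * float(np.sum(WR * d2_l))
        pos += L_dim
    else:
        gX = 2.0 * theta0 * (W @ X) + X
        grad[: N * L_dim] = gX.ravel()
        pos = N * L_dim
        grad[pos] = theta0 * float(np.sum(W * G)); pos += 1
    grad[pos] = theta3 * float(np.sum(W)); pos += 1
    grad[pos] = sigma2 * float(np.trace(W))
    return f, grad


class GPLVM:
    """Latent-variable model of a backbone conformational ensemble.

    Parameters
    ----------
    data : DataMatrix or ndarray (N x D)
        Superposed, flattened ensemble coordinates.  An ndarray is accepted
        for non-structural use; a :class:`~flexibal.structures.DataMatrix`
        additionally lets the results reconstruct full backbones.
    n_latent : int
        Latent dimensionality L (default 2); must satisfy 1 <= L < N.
    kernel : {"rbf", "linear"}
        "rbf" is the composite RBF + bias kernel; "linear" recovers
        probabilistic PCA and is mainly a cross-check.

    Examples
    --------
    >>> model = GPLVM(data_matrix, n_latent=2)
    >>> res = model.fit(seed=0)
    >>> y_star, var = res.reconstruct(res.X[0])
    """

    def __init__(self, data: DataMatrix | np.ndarray, n_latent: int = 2,
                 kernel: KernelName = "rbf"):
        if isinstance(data, DataMatrix):
            self.data = data
            Y = data.values
            self._column_means = data.column_means
        else:
            Y = np.atleast_2d(np.asarray(data, dtype=float))
            self.data = None
            self._column_means = Y.mean(axis=0)
        if Y.ndim != 2:
            raise ValueError("data must be a 2-D N x D matrix")
        N = Y.shape[0]
        if n_latent < 1:
            raise ValueError(f"n_latent must be >= 1; got {n_latent}")
        if N > 1 and n_latent >= N:
            # prediction with manually supplied latents tolerates L >= N;
            # fitting does not (checked again in fit)
            raise ValueError(f"n_latent must satisfy 1 <= L < N={N}; got {n_latent}")
        if kernel not in ("rbf", "linear"):
            raise ValueError(f"unknown kernel {kernel!r}")
        self.Y = Y
        self.Y_centered = Y - self._column_means
        self.n_latent = int(n_latent)
        self.kernel: KernelName = kernel

    # -- initialisation ----------------------------------------------------

    def _init_latents(self, seed: int) -> np.ndarray:
        """Top-L principal component scores, scaled to unit variance.

        Degenerate directions (zero singular value) get small random
        coordinates so the optimiser is not started on a razor edge.
        """
        rng = np.random.default_rng(seed)
        U, S, _ = np.linalg.svd(self.Y_centered, full_matrices=False)
        L = self.n_latent
        X0 = U[:, :L] * S[:L]
        std = X0.std(axis=0)
        for l in range(L):
            if std[l] < 1e-12:
                X0[:, l] = 1e-3 * rng.standard_normal(X0.shape[0])
            else:
                X0[:, l] = X0[:, l] / std[l]
        return X0

    def fit(self, seed: int = 0, maxiter: int = 1000,
            init_noise_variance: float | None = None) -> "GPLVMResults":
        """Jointly optimise latents, kernel parameters and noise variance.

        Positivity of the hyperparameters is structural: the optimiser works
        on their logarithms.  Non-convergence within ``maxiter`` L-BFGS
        iterations is reported as a warning on the results object, not an
        error.
        """
        N, D = self.Y.shape
        L_dim = self.n_latent
        if L_dim >= N:
            raise ValueError(f"fitting requires n_latent < N={N}; got {L_dim}")
        X0 = self._init_latents(seed)
        data_var = float(np.var(self.Y_centered)) or 1.0
        if init_noise_variance is None:
            init_noise_variance = 0.01 * data_var

        packed = [X0.ravel(), [np.log(data_var)]]
        if self.kernel == "rbf":
            packed.append(np.zeros(L_dim))            # log theta_l = 0
        packed.append([np.log(0.1 * data_var)])       # log theta3
        packed.append([np.log(init_noise_variance)])  # log sigma2
        vec0 = np.concatenate([np.asarray(p, dtype=float).ravel() for p in packed])

        result = minimize(
            _objective_and_grad, vec0, args=(self.Y_centered, N, L_dim, self.kernel),
            method="L-BFGS-B", jac=True,
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8},
        )

        vec = result.x
        X = vec[: N * L_dim].reshape(N, L_dim).copy()
        pos = N * L_dim
        theta0 = float(np.exp(vec[pos])); pos += 1
        if self.kernel == "rbf":
            theta_l = np.exp(vec[pos: pos + L_dim]); pos += L_dim
        else:
            theta_l = np.ones(L_dim)
        theta3 = float(np.exp(vec[pos])); pos += 1
        sigma2 = float(np.exp(vec[pos]))
        params = KernelParams(theta0=theta0, theta_l=theta_l, theta3=theta3)

        return GPLVMResults(
            model=self, X=X, params=params, noise_variance=sigma2,
            neg_log_posterior=float(result.fun), converged=bool(result.success),
            n_iterations=int(result.nit),
            final_grad_norm=float(np.max(np.abs(result.jac))),
        )


@dataclass
class GPLVMResults:
    """Fitted latent-variable model: estimates, diagnostics, reconstruction."""

    model: GPLVM
    X: np.ndarray
    params: KernelParams
    noise_variance: float
    neg_log_posterior: float
    converged: bool
    n_iterations: int
    final_grad_norm: float
    _chol: np.ndarray | None = field(default=None, repr=False)
    _alpha: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self._refresh_cache()
        if not self.converged:
            import warnings
            warnings.warn(
                f"optimiser did not report convergence "
                f"(final max |grad| = {self.final_grad_norm:.3g})",
                RuntimeWarning, stacklevel=2,
            )

    def _refresh_cache(self) -> None:
        N = self.X.shape[0]
        K = kernel_matrix(self.X, self.X, self.params, self.model.kernel)
        M = K + self.noise_variance * np.eye(N)
        L, _ = _chol_with_jitter(M)
        self._chol = L
        self._alpha = cho_solve((L, True), self.model.Y_centered)

    # -- conveniences ------------------------------------------------------

    @property
    def kernel(self) -> KernelName:
        return self.model.kernel

    @property
    def column_means(self) -> np.ndarray:
        return self.model._column_means

    @property
    def latent_ranges(self) -> np.ndarray:
        """(L, 2) array of per-dimension (min, max) over the fitted latents."""
        return np.stack([self.X.min(axis=0), self.X.max(axis=0)], axis=1)

    def set_noise_variance(self, sigma2: float) -> None:
        """Override the noise variance (refreshes the cached factorisation)."""
        if sigma2 < 0:
            raise ValueError("noise variance must be non-negative")
        self.noise_variance = float(sigma2)
        self._refresh_cache()

    # -- prediction --------------------------------------------------------

    def reconstruct(self, x_star: np.ndarray) -> tuple[np.ndarray, float]:
        """Predictive mean coordinates and shared predictive variance at x*.

        The mean re-adds the stored column means after centred-data
        regression, so absolute Cartesian positions are recovered.
        """
        x_star = np.atleast_2d(np.asarray(x_star, dtype=float))
        if x_star.shape != (1, self.X.shape[1]):
            raise ValueError(
                f"x_star must be a single point of dimension {self.X.shape[1]}"
            )
        k_star = kernel_matrix(x_star, self.X, self.params, self.model.kernel)
        mean = self.column_means + (k_star @ self._alpha)[0]
        v = solve_triangular(self._chol, k_star[0], lower=True)
        k_ss = float(kernel_diag(x_star, self.params, self.model.kernel)[0])
        var = max(k_ss - float(v @ v), 0.0)
        return mean, var

    def reconstruct_structure(self, x_star: np.ndarray) -> BackboneStructure:
        """Reconstruct a full backbone (requires DataMatrix-backed model)."""
        if self.model.data is None:
            raise ValueError("model was built from a bare matrix, not a DataMatrix")
        mean, _ = self.reconstruct(x_star)
        return self.model.data.unflatten(mean)

    def latent_step_sigma(self, scale: float = 0.001) -> np.ndarray:
        """Per-dimension proposal standard deviation for latent moves.

        ``scale`` times the span of the fitted latents in each dimension
        (default 0.001, the published step rule).
        """
        rng = self.X.max(axis=0) - self.X.min(axis=0)
        if np.any(rng <= 0):
            bad = int(np.argmin(rng))
            raise ValueError(
                f"latent dimension {bad} has zero range; refit the model or "
                "supply a proposal sigma manually"
            )
        return scale * rng

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        N, D = self.model.Y.shape
        lines = [
            "Backbone latent-variable model",
            "=" * 46,
            f"{'Observations (structures)':<34}{N:>12d}",
            f"{'Features (coordinates, D)':<34}{D:>12d}",
            f"{'Latent dimensions (L)':<34}{self.X.shape[1]:>12d}",
            f"{'Kernel':<34}{self.model.kernel:>12}",
            f"{'Neg. log posterior':<34}{self.neg_log_posterior:>12.4f}",
            f"{'Converged':<34}{str(self.converged):>12}",
            f"{'Optimiser iterations':<34}{self.n_iterations:>12d}",
            "-" * 46,
            f"{'theta0 (amplitude)':<34}{self.params.theta0:>12.6g}",
        ]
        for l, w in enumerate(self.params.theta_l):
            lines.append(f"{f'theta_{l + 1} (dim {l + 1} weight)':<34}{w:>12.6g}")
        lines.append(f"{'theta3 (bias)':<34}{self.params.theta3:>12.6g}")
        lines.append(f"{'noise variance sigma2':<34}{self.noise_variance:>12.6g}")
        lines.append("-" * 46)
        for l in range(self.X.shape[1]):
            lo, hi = self.X[:, l].min(), self.X[:, l].max()
            lines.append(f"{f'latent dim {l + 1} range':<34}[{lo:+.4f}, {hi:+.4f}]")
        return "\n".join(lines)

    # -- serialisation -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Serialise the fitted model to a versioned JSON archive."""
        payload = {
            "format_version": _FORMAT_VERSION,
            "kernel": self.model.kernel,
            "X": self.X.tolist(),
            "theta0": self.params.theta0,
            "theta_l": self.params.theta_l.tolist(),
            "theta3": self.params.theta3,
            "noise_variance": self.noise_variance,
            "neg_log_posterior": self.neg_log_posterior,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "final_grad_norm": self.final_grad_norm,
            "Y": self.model.Y.tolist(),
            "column_means": self.column_means.tolist(),
        }
        if self.model.data is not None:
            topo = self.model.data.topology
            payload["topology"] = {
                "residue_ids": list(topo.residue_ids),
                "chain_ids": list(topo.chain_ids),
                "sequence": topo.sequence,
                "coords": topo.coords.tolist(),
            }
            payload["topology_hash"] = topology_hash(topo)
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "GPLVMResults":
        payload = json.loads(Path(path).read_text())
        version = payload.get("format_version")
        if version != _FORMAT_VERSION:
            raise ValueError(f"unsupported model archive version {version!r}")
        Y = np.asarray(payload["Y"], dtype=float)
        if "topology" in payload:
            from .structures import StructureEnsemble, build_data_matrix

            topo = payload["topology"]
            template = BackboneStructure(
                residue_ids=tuple(topo["residue_ids"]),
                chain_ids=tuple(topo["chain_ids"]),
                coords=np.asarray(topo["coords"], dtype=float),
                sequence=topo["sequence"],
            )
            data = DataMatrix(
                values=Y, column_means=np.asarray(payload["column_means"]),
                atom_index={}, topology=template,
            )
            model = GPLVM(data, n_latent=len(payload["X"][0]),
                          kernel=payload["kernel"])
        else:
            model = GPLVM(Y, n_latent=len(payload["X"][0]),
                          kernel=payload["kernel"])
        return cls(
            model=model,
            X=np.asarray(payload["X"], dtype=float),
            params=KernelParams(
                theta0=payload["theta0"],
                theta_l=np.asarray(payload["theta_l"], dtype=float),
                theta3=payload["theta3"],
            ),
            noise_variance=payload["noise_variance"],
            neg_log_posterior=payload["neg_log_posterior"],
            converged=payload["converged"],
            n_iterations=payload["n_iterations"],
            final_grad_norm=payload["final_grad_norm"],
        )

    def export_latents_tsv(self, path: str | Path) -> None:
        """Write the fitted latent coordinates as TSV (for trajectory plots)."""
        import pandas as pd

        cols = {f"latent_{l + 1}": self.X[:, l] for l in range(self.X.shape[1])}
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def topology_hash(structure: BackboneStructure) -> str:
    h = hashlib.sha256()
    h.update("|".join(structure.residue_ids).encode())
    h.update("|".join(structure.chain_ids).encode())
    h.update(structure.sequence.encode())
    return h.hexdigest()[:16]


def fit_gplvm(data: DataMatrix | np.ndarray, n_latent: int = 2,
              kernel: KernelName = "rbf", seed: int = 0,
              maxiter: int = 1000) -> GPLVMResults:
    """Convenience wrapper: build a :class:`GPLVM` and fit it."""
    return GPLVM(data, n_latent=n_latent, kernel=kernel).fit(seed=seed, maxiter=maxiter)


def latent_step_sigma(results: GPLVMResults, scale: float = 0.001) -> np.ndarray:
    """Functional alias for :meth:`GPLVMResults.latent_step_sigma`."""
    return results.latent_step_sigma(scale=scale)
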