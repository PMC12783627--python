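"""Image-quality and segmentation metrics.

Generation quality: Frechet distance between Gaussian fits of embedded image
features (FID), the Inception Score computed from a table of per-image class
posteriors, and PSNR. The embedder and classifier are pluggable contracts —
desk-scale tests use the identity embedder and a small fixed-seed network, a
pre-trained deep model can be supplied at runtime. Segmentation quality:
accuracy, precision, recall, F1 and Dice from pixel confusion counts (F1 and
Dice coincide on binary masks; both names are reported because both are used
in practice).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = [
    "GaussianStats",
    "ConfusionCounts",
    "feature_stats",
    "fid",
    "inception_score",
    "psnr",
    "confusion_metrics",
    "confusion_from_masks",
    "IdentityEmbedder",
    "RandomProjectionClassifier",
    "PSNR_CAP_DB",
]

PSNR_CAP_DB = 99.0  # reported value for identical images (MSE = 0)


@dataclass
class GaussianStats:
    """Mean vector and covariance matrix of embedded image features."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.sigma.shape != (self.mu.size, self.mu.size):
            raise ValueError("sigma must be square and match mu")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-8):
            raise ValueError("sigma must be symmetric")
        eigmin = float(np.linalg.eigvalsh(self.sigma).min())
        if eigmin < -1e-8:
            raise ValueError(f"sigma not positive semidefinite (min eig {eigmin})")


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


class IdentityEmbedder:
    """Flattens each image into its feature vector."""

    def embed(self, images) -> np.ndarray:
        arr = np.asarray(images, dtype=float)
        return arr.reshape(arr.shape[0], -1)


class RandomProjectionClassifier:
    """Fixed-seed random linear classifier producing class posteriors.

    A desk-scale stand-in for a pre-trained classifier: deterministic,
    download-free, and sufficient to exercise the Inception Score and
    mode-collapse machinery.
    """

    def __init__(self, n_classes: int = 8, n_features: int = 64, seed: int = 0):
        self.n_classes = n_classes
        self.n_features = n_features
        self._rng_seed = seed
        self._weights: np.ndarray | None = None

    def _ensure_weights(self, dim: int) -> np.ndarray:
        if self._weights is None or self._weights.shape[0] != dim:
            rng = np.random.default_rng(self._rng_seed)
            proj = rng.normal(size=(dim, self.n_features))
            head = rng.normal(size=(self.n_features, self.n_classes))
            self._weights = proj @ head / np.sqrt(dim)
        return self._weights

    def predict_proba(self, images) -> np.ndarray:
        arr = np.asarray(images, dtype=float).reshape(len(images), -1)
        logits = arr @ self._ensure_weights(arr.shape[1])
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        return p / p.sum(axis=1, keepdims=True)


def feature_stats(images, embedder=None) -> GaussianStats:
    """Sample mean and covariance (denominator n-1) of embedded features."""
    embedder = embedder or IdentityEmbedder()
    feats = np.asarray(embedder.embed(images), dtype=float)
    if feats.ndim != 2 or feats.shape[0] < 2:
        raise ValueError("need at least 2 images to estimate feature statistics")
    mu = feats.mean(axis=0)
    sigma = np.cov(feats, rowvar=False, ddof=1)
    sigma = np.atleast_2d(sigma)
    return GaussianStats(mu, 0.5 * (sigma + sigma.T))


def fid(a: GaussianStats, b: GaussianStats) -> float:
    """||mu_a - mu_b||^2 + Tr(S_a + S_b - 2 (S_a S_b)^{1/2})."""
    if a.mu.shape != b.mu.shape:
        raise ValueError("dimension mismatch between statistics")
    diff = a.mu - b.mu
    prod = a.sigma @ b.sigma
    covmean = linalg.sqrtm(prod)
    if np.iscomplexobj(covmean):
        imag_max = float(np.abs(covmean.imag).max())
        if imag_max > 1e-6 * max(1.0, float(np.abs(covmean.real).max())):
            raise FloatingPointError(
                f"matrix square root strongly indefinite (max imag {imag_max})")
        covmean = covmean.real
    value = float(diff @ diff + np.trace(a.sigma + b.sigma - 2.0 * covmean))
    if value < 0:
        # rank-deficient covariances (few images, many features) leave
        # numerical residue in the matrix square root; clip within a
        # dimension-scaled tolerance, fail beyond it
        tol = max(1e-8, 1e-6 * a.mu.size)
        if value < -tol:
            raise FloatingPointError(f"FID evaluated to {value}")
        value = 0.0
    return value


def inception_score(probs) -> float:
    """exp of the mean KL divergence between row posteriors and their marginal."""
    p = np.asarray(probs, dtype=float)
    if p.ndim != 2:
        raise ValueError("probability table must be 2-D (images x classes)")
    if np.any(p < 0):
        raise ValueError("probabilities must be >= 0")
    row_sums = p.sum(axis=1)
    if not np.allclose(row_sums, 1.0, atol=1e-8):
        raise ValueError("each row must sum to 1")
    marginal = p.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio = np.where(p > 0, np.log(p / marginal), 0.0)
    kl = (p * log_ratio).sum(axis=1)
    return float(np.exp(kl.mean()))


def psnr(a, b, max_val: float = 1.0) -> float:
    """10 log10(max^2 / MSE) in dB; identical images report the 99 dB cap."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    if max_val <= 0:
        raise ValueError("max_val must be > 0")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return PSNR_CAP_DB
    return min(PSNR_CAP_DB, 10.0 * np.log10(max_val**2 / mse))


def confusion_metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Accuracy/precision/recall/F1/Dice; undefined metrics reported as None."""
    if c.total < 1:
        return {k: None for k in ("accuracy", "precision", "recall", "f1", "dice")}
    out: dict[str, float | None] = {}
    out["accuracy"] = (c.tp + c.tn) / c.total
    out["precision"] = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    out["recall"] = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    # 2PR/(P+R) algebraically equals 2TP/(2TP+FP+FN); computing from the
    # counts keeps the F1 == Dice identity exact in floating point
    denom = 2 * c.tp + c.fp + c.fn
    out["f1"] = 2.0 * c.tp / denom if denom > 0 else None
    out["dice"] = out["f1"]
    return out


def confusion_from_masks(predicted, truth) -> ConfusionCounts:
    pred = np.asarray(predicted).astype(bool)
    true = np.asarray(truth).astype(bool)
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {true.shape}")
    return ConfusionCounts(
        tp=int(np.sum(pred & true)),
        tn=int(np.sum(~pred & ~true)),
        fp=int(np.sum(pred & ~true)),
        fn=int(np.sum(~pred & true)),
    )
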