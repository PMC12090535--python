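"""Variance–covariance structures for multi-kernel genomic prediction.

Builds every relationship matrix the regression models use: the additive
genomic relationship matrix (GRM) from centred SNP codes, the epistatic
kernel as the Hadamard square of the GRM, the dominance kernel from a
heterozygosity recoding, the linear transcriptome kernel, the Gaussian
(RKHS) kernel, 0/1 incidence expansions from lines/environments to
observations, and the multi-environment genotype-by-environment block
kernel.

All kernels are returned as :class:`KernelMatrix`, which enforces symmetry
and an eigenvalue floor (kernels must be positive semi-definite up to float
noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from ._util import warn

__all__ = [
    "GenotypePanel",
    "KernelMatrix",
    "IncidenceMatrix",
    "center_genotypes",
    "grm_linear",
    "epistasis_kernel",
    "dominance_kernel",
    "transcriptome_kernel",
    "gaussian_kernel",
    "median_bandwidth",
    "incidence_matrix",
    "gxe_block_kernel",
]

#: relative eigenvalue floor: lambda_min >= -PSD_RTOL * lambda_max
PSD_RTOL = 1e-8

KERNEL_KINDS = ("G", "EPI", "A", "T", "GAUSS", "GxE")


@dataclass
class GenotypePanel:
    """Biallelic SNP genotypes for a panel of (largely inbred) lines.

    Parameters
    ----------
    line_ids
        Ordered, unique line identifiers.
    codes
        ``l x m`` matrix of allele-dosage codes in {0, 1, 2} (count of the
        alternate allele).  Mean-imputed values from missing calls may be
        non-integer.  Codes supplied as {-1, 0, 1} are shifted to {0, 1, 2}
        on construction.
    """

    line_ids: np.ndarray
    codes: np.ndarray
    marker_ids: np.ndarray | None = None

    def __post_init__(self):
        self.line_ids = np.asarray(self.line_ids, dtype=object)
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D (lines x markers) matrix")
        if len(self.line_ids) != self.codes.shape[0]:
            raise ValueError("line_ids length does not match codes rows")
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("line_ids must be unique")
        if self.marker_ids is None:
            self.marker_ids = np.array(
                [f"m{k}" for k in range(self.codes.shape[1])], dtype=object
            )
        else:
            self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.codes = _normalise_codes(self.codes)

    @property
    def n_lines(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    @property
    def allele_freq(self) -> np.ndarray:
        """Per-marker alternate-allele frequency p_k = (2l)^-1 sum_i X_ik."""
        return self.codes.mean(axis=0) / 2.0

    @property
    def heterozygosity(self) -> np.ndarray:
        """Per-marker observed heterozygote fraction (code == 1)."""
        return (self.codes == 1).mean(axis=0)


def _normalise_codes(codes: np.ndarray) -> np.ndarray:
    """Map the {-1,0,1} dialect onto {0,1,2}; reject ambiguous/invalid sets."""
    finite = codes[np.isfinite(codes)]
    if finite.size == 0:
        raise ValueError("genotype matrix contains no finite codes")
    vals = set(np.unique(finite[finite == np.round(finite)]).tolist())
    lo, hi = finite.min(), finite.max()
    if lo < -1 or hi > 2:
        raise ValueError(f"genotype codes outside both dialects: min={lo}, max={hi}")
    if lo < 0 and hi > 1:
        raise ValueError("genotype codes mix the {-1,0,1} and {0,1,2} dialects")
    if lo < 0:
        return codes + 1.0
    if vals and vals <= {0.0, 1.0}:
        raise ValueError(
            "genotype codes limited to {0,1}: dialect is ambiguous; "
            "recode explicitly as {0,1,2} or {-1,0,1}"
        )
    return codes


@dataclass
class KernelMatrix:
    """Symmetric PSD covariance structure over lines or observations.

    ``kind`` tags the provenance: ``G`` additive GRM, ``EPI`` epistatic
    Hadamard square, ``A`` dominance, ``T`` transcriptome linear kernel,
    ``GAUSS`` Gaussian RKHS kernel (with ``bandwidth``), ``GxE``
    environment-blocked expansion.
    """

    entries: np.ndarray
    axis_ids: np.ndarray
    kind: str
    bandwidth: float | None = None

    def __post_init__(self):
        self.entries = np.asarray(self.entries, dtype=float)
        self.axis_ids = np.asarray(self.axis_ids, dtype=object)
        if self.kind not in KERNEL_KINDS:
            raise ValueError(f"unknown kernel kind {self.kind!r}; expected one of {KERNEL_KINDS}")
        n = self.entries.shape[0]
        if self.entries.ndim != 2 or self.entries.shape[1] != n:
            raise ValueError("kernel entries must be square")
        if len(self.axis_ids) != n:
            raise ValueError("axis_ids length does not match kernel dimension")
        if len(set(self.axis_ids)) != n:
            raise ValueError("kernel axis_ids must be unique")
        if not np.allclose(self.entries, self.entries.T, atol=1e-8):
            raise ValueError("kernel is not symmetric")
        self.entries = 0.5 * (self.entries + self.entries.T)

    @property
    def n(self) -> int:
        return self.entries.shape[0]

    def validate_psd(self, rtol: float = PSD_RTOL) -> None:
        """Raise if the minimum eigenvalue is materially negative."""
        w = np.linalg.eigvalsh(self.entries)
        lam_max = max(w[-1], 1e-300)
        if w[0] < -rtol * lam_max:
            raise ValueError(
                f"kernel ({self.kind}) is not PSD: lambda_min={w[0]:.3g}, lambda_max={lam_max:.3g}"
            )

    def repaired(self, rtol: float = PSD_RTOL) -> "KernelMatrix":
        """Clip slightly negative eigenvalues (float noise) to zero, warning."""
        w, U = np.linalg.eigh(self.entries)
        lam_max = max(w[-1], 1e-300)
        if w[0] >= 0:
            return self
        if w[0] < -rtol * lam_max:
            raise ValueError(
                f"kernel ({self.kind}) eigenvalue {w[0]:.3g} below repair floor "
                f"(-{rtol:g} * {lam_max:.3g})"
            )
        warn("KERNEL_PSD_REPAIR", f"clipped negative eigenvalues >= {w[0]:.3g} in {self.kind} kernel")
        ent = (U * np.clip(w, 0.0, None)) @ U.T
        return KernelMatrix(0.5 * (ent + ent.T), self.axis_ids, self.kind, self.bandwidth)

    def mean_diag(self) -> float:
        return float(np.mean(np.diag(self.entries)))


@dataclass
class IncidenceMatrix:
    """0/1 design mapping observations to lines (or environments).

    Every row has exactly one 1; column sums are the replicate counts.
    """

    entries: np.ndarray
    row_ids: np.ndarray
    col_ids: np.ndarray

    def __post_init__(self):
        self.entries = np.asarray(self.entries, dtype=float)
        self.row_ids = np.asarray(self.row_ids, dtype=object)
        self.col_ids = np.asarray(self.col_ids, dtype=object)
        if self.entries.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("incidence shape does not match row/col ids")
        if not np.isin(self.entries, (0.0, 1.0)).all():
            raise ValueError("incidence entries must be 0/1")
        if not (self.entries.sum(axis=1) == 1).all():
            raise ValueError("every observation must map to exactly one group")

    @property
    def replicate_counts(self) -> np.ndarray:
        return self.entries.sum(axis=0)


# ---------------------------------------------------------------------------
# genotype-derived kernels


def center_genotypes(panel: GenotypePanel) -> tuple[np.ndarray, np.ndarray]:
    """Centre allele-dosage codes: W_ik = X_ik - 2 p_k.

    Monomorphic markers (p_k in {0, 1}) carry no information and break the
    GRM denominator; they are dropped with a coded warning.

    Returns
    -------
    W : (l, m') centred matrix over the retained (polymorphic) markers
    keep : boolean mask of retained marker columns
    """
    p = panel.allele_freq
    keep = (p > 0.0) & (p < 1.0)
    if not keep.all():
        warn("MONOMORPHIC_DROPPED", f"dropped {int((~keep).sum())} monomorphic marker(s)")
    W = panel.codes[:, keep] - 2.0 * p[keep]
    return W, keep


def grm_linear(panel: GenotypePanel) -> KernelMatrix:
    """Additive genomic relationship matrix G = W W^T / (2 sum_k p_k(1-p_k)).

    The VanRaden scaling makes the mean diagonal equal 1 + f, where f is the
    panel's inbreeding coefficient.
    """
    W, keep = center_genotypes(panel)
    if keep.sum() < 1:
        raise ValueError("all markers are monomorphic; GRM undefined")
    p = panel.allele_freq[keep]
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("zero GRM denominator (no polymorphic markers)")
    G = (W @ W.T) / denom
    return KernelMatrix(G, panel.line_ids, kind="G")


def epistasis_kernel(G: KernelMatrix) -> KernelMatrix:
    """Epistatic (gene-by-gene) kernel: Hadamard square G ∘ G.

    PSD by the Schur product theorem since G is PSD.
    """
    if G.entries.shape[0] != G.entries.shape[1]:
        raise ValueError("epistasis kernel requires a square GRM")
    return KernelMatrix(G.entries * G.entries, G.axis_ids, kind="EPI")


def dominance_kernel(panel: GenotypePanel) -> KernelMatrix:
    """Dominance kernel from the homozygosity indicator recoding.

    Markers are recoded 1 for homozygotes (AA, BB) and 0 for heterozygotes
    (AB); the indicator columns are centred and cross-multiplied, and the
    kernel is rescaled to mean diagonal 1 so its variance component is
    comparable with the other terms.
    """
    het = (panel.codes == 1.0).astype(float)
    if het.sum() == 0:
        raise ValueError(
            "panel contains no heterozygous calls; the dominance design is "
            "constant — drop the dominance term for fully inbred panels"
        )
    dom = 1.0 - het  # 1 = homozygous, 0 = heterozygous
    dc = dom - dom.mean(axis=0)
    informative = dc.std(axis=0) > 0
    dc = dc[:, informative]
    A = dc @ dc.T
    md = float(np.mean(np.diag(A)))
    if md <= 0:
        raise ValueError("dominance kernel degenerate (no variation in heterozygosity)")
    return KernelMatrix(A / md, panel.line_ids, kind="A")


def transcriptome_kernel(
    abundances: np.ndarray, axis_ids: Sequence | np.ndarray
) -> KernelMatrix:
    """Linear kernel over normalised transcript abundances.

    Genes are standardised (mean 0, sd 1; zero-variance genes dropped) and
    the cross-product is divided by the gene count, giving mean diagonal 1.
    """
    Xt = np.asarray(abundances, dtype=float)
    if Xt.ndim != 2:
        raise ValueError("abundance matrix must be 2-D (rows x genes)")
    if not np.isfinite(Xt).all():
        raise ValueError("abundance matrix contains missing values")
    sd = Xt.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all genes have zero variance; transcriptome kernel undefined")
    if not keep.all():
        warn("ZERO_VARIANCE_GENES", f"dropped {int((~keep).sum())} zero-variance gene(s)")
    Z = (Xt[:, keep] - Xt[:, keep].mean(axis=0)) / sd[keep]
    T = (Z @ Z.T) / keep.sum()
    return KernelMatrix(T, np.asarray(axis_ids, dtype=object), kind="T")


def gaussian_kernel(
    X: np.ndarray,
    h: float,
    axis_ids: Sequence | np.ndarray | None = None,
    scale_by_features: bool = False,
) -> KernelMatrix:
    """Gaussian RKHS kernel K_ij = exp(-d²_ij / h) over row profiles.

    ``d²`` is the squared Euclidean distance between rows (divided by the
    number of features when ``scale_by_features``).  The bandwidth ``h``
    controls how fast correlation between lines decays with marker distance;
    a single Gaussian term captures additive plus cryptic non-additive
    (epistatic, dominance) genetic effects together.
    """
    if h <= 0:
        raise ValueError("Gaussian bandwidth h must be positive")
    X = np.asarray(X, dtype=float)
    d2 = squareform(pdist(X, metric="sqeuclidean"))
    if scale_by_features:
        d2 = d2 / X.shape[1]
    K = np.exp(-d2 / h)
    np.fill_diagonal(K, 1.0)
    if axis_ids is None:
        axis_ids = np.arange(X.shape[0])
    return KernelMatrix(K, np.asarray(axis_ids, dtype=object), kind="GAUSS", bandwidth=float(h))


def median_bandwidth(X: np.ndarray, scale_by_features: bool = False) -> float:
    """Median heuristic: median of the nonzero pairwise squared distances."""
    X = np.asarray(X, dtype=float)
    d2 = pdist(X, metric="sqeuclidean")
    if scale_by_features:
        d2 = d2 / X.shape[1]
    nz = d2[d2 > 0]
    if nz.size == 0:
        raise ValueError("all rows identical; median bandwidth undefined")
    return float(np.median(nz))


# ---------------------------------------------------------------------------
# incidence and G x E


def incidence_matrix(
    obs_ids: Sequence,
    group_of: Mapping,
    groups: Sequence,
) -> IncidenceMatrix:
    """0/1 matrix relating observations (rows) to groups (columns).

    ``group_of`` maps each observation id to its line or environment; the
    column order follows ``groups``.
    """
    groups = list(groups)
    index = {g: j for j, g in enumerate(groups)}
    Z = np.zeros((len(obs_ids), len(groups)))
    for i, obs in enumerate(obs_ids):
        if obs not in group_of:
            raise KeyError(f"observation {obs!r} has no group assignment")
        g = group_of[obs]
        if g not in index:
            raise KeyError(f"observation {obs!r} maps to unknown group {g!r}")
        Z[i, index[g]] = 1.0
    return IncidenceMatrix(Z, np.asarray(list(obs_ids), dtype=object), np.asarray(groups, dtype=object))


def gxe_block_kernel(
    G: KernelMatrix, Zg: IncidenceMatrix, Ze: IncidenceMatrix
) -> KernelMatrix:
    """Genotype-by-environment kernel (Z_g G Z_gᵀ) ∘ (Z_E Z_Eᵀ).

    The Hadamard product with the environment-sharing indicator zeroes every
    cross-environment entry, leaving the observation-expanded genomic kernel
    within each environment: with observations sorted by environment this is
    the block-diagonal multi-environment single-variance structure.
    """
    if not np.array_equal(Zg.row_ids, Ze.row_ids):
        raise ValueError("line and environment incidence matrices index different observations")
    if not np.array_equal(Zg.col_ids, G.axis_ids):
        raise ValueError("incidence columns do not match kernel axis ids")
    Gobs = Zg.entries @ G.entries @ Zg.entries.T
    same_env = Ze.entries @ Ze.entries.T
    return KernelMatrix(Gobs * same_env, Zg.row_ids, kind="GxE", bandwidth=G.bandwidth)
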