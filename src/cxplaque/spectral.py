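"""Reference emission fingerprints and per-voxel linear unmixing.

Six-marker wholemount immunofluorescence resolves four connexin channels
plus the astrocyte (GFAP) and vessel (GS isolectin B4) markers by spectral
imaging: each fluorophore contributes its emission fingerprint to every
voxel, and per-voxel linear unmixing recovers the fluorophore abundances.

The fingerprint matrix A is K x L (fluorophores x spectral bins), rows
normalized to unit sum.  Unmixing solves, independently per voxel,

    min_x || s - A^T x ||_2     subject to x >= 0 (default),

where s is the voxel's measured spectrum.  Nonnegativity reflects that
abundances are physical dye quantities; an unconstrained mode is kept for
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .stacks import LambdaStack, default_bin_centers

#: Fluorophore -> marker assignment used by the six-marker protocol.
MARKER_ASSIGNMENT = {
    "AMCA": "GS-lectin",
    "Alexa488": "Cx43",
    "Alexa532": "Cx26",
    "Cy3": "Cx30",
    "Alexa594": "Cx45",
    "Cy5": "GFAP",
}

#: Emission peak wavelengths (nm) used by the default dye model.  These are
#: configuration defaults modeling the named dyes, fully overridable.
DEFAULT_PEAKS_NM = {
    "AMCA": 448.0,
    "Alexa488": 519.0,
    "Alexa532": 553.0,
    "Cy3": 569.0,
    "Alexa594": 617.0,
    "Cy5": 670.0,
}

CONNEXINS = ("Cx26", "Cx30", "Cx43", "Cx45")


class GridMismatchError(ValueError):
    """Spectral bin grids of two objects do not match."""


class CollinearSpectraError(ValueError):
    """Fingerprint matrix is rank deficient."""


def skewed_gaussian(wavelengths: np.ndarray, peak: float,
                    sigma_blue: float = 14.0, sigma_red: float = 32.0) -> np.ndarray:
    """Asymmetric Gaussian emission curve: steep blue edge, long red tail."""
    wl = np.asarray(wavelengths, dtype=float)
    sigma = np.where(wl < peak, sigma_blue, sigma_red)
    return np.exp(-0.5 * ((wl - peak) / sigma) ** 2)


@dataclass
class ReferenceSpectraSet:
    """Per-fluorophore emission fingerprints over the spectral bin grid.

    ``matrix`` is K x L, each row nonnegative and normalized to unit sum.
    """

    fluorophores: tuple[str, ...]
    matrix: np.ndarray
    bin_centers: np.ndarray

    def __post_init__(self) -> None:
        self.fluorophores = tuple(self.fluorophores)
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.bin_centers = np.asarray(self.bin_centers, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("fingerprint matrix must be 2D (fluorophore x bin)")
        if self.matrix.shape != (len(self.fluorophores), self.bin_centers.size):
            raise ValueError(
                f"matrix shape {self.matrix.shape} inconsistent with "
                f"{len(self.fluorophores)} fluorophores x {self.bin_centers.size} bins")
        if np.any(self.matrix < 0):
            raise ValueError("fingerprints must be nonnegative")
        sums = self.matrix.sum(axis=1)
        if np.any(sums <= 0):
            bad = [f for f, s in zip(self.fluorophores, sums) if s <= 0]
            raise ValueError(f"degenerate all-zero fingerprint(s): {bad}")
        self.matrix = self.matrix / sums[:, None]
        self._check_rank()

    def _check_rank(self) -> None:
        rank = np.linalg.matrix_rank(self.matrix)
        if rank < len(self.fluorophores):
            # name the most collinear pair for the error message
            unit = self.matrix / np.linalg.norm(self.matrix, axis=1, keepdims=True)
            cos = unit @ unit.T
            np.fill_diagonal(cos, -np.inf)
            i, j = np.unravel_index(np.argmax(cos), cos.shape)
            raise CollinearSpectraError(
                f"fingerprint matrix is rank deficient (rank {rank} < "
                f"{len(self.fluorophores)}); most collinear pair: "
                f"{self.fluorophores[i]} / {self.fluorophores[j]}")

    @property
    def condition_number(self) -> float:
        """Condition number of the fingerprint matrix (well-posedness of unmixing)."""
        return float(np.linalg.cond(self.matrix))

    def reorder(self, fluorophores) -> "ReferenceSpectraSet":
        idx = [self.fluorophores.index(f) for f in fluorophores]
        return ReferenceSpectraSet(tuple(fluorophores), self.matrix[idx], self.bin_centers)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.matrix, index=list(self.fluorophores),
                          columns=[f"{c:.4f}" for c in self.bin_centers])
        df.index.name = "fluorophore"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "ReferenceSpectraSet":
        df = pd.read_csv(path, index_col=0)
        return cls(tuple(df.index), df.to_numpy(float),
                   np.array([float(c) for c in df.columns]))


def default_reference_spectra(bin_centers: np.ndarray | None = None,
                              fluorophores=tuple(DEFAULT_PEAKS_NM),
                              peaks: dict[str, float] | None = None) -> ReferenceSpectraSet:
    """Model fingerprints for the six-dye panel on the default bin grid."""
    if bin_centers is None:
        bin_centers = default_bin_centers()
    peaks = {**DEFAULT_PEAKS_NM, **(peaks or {})}
    matrix = np.stack([skewed_gaussian(bin_centers, peaks[f]) for f in fluorophores])
    return ReferenceSpectraSet(tuple(fluorophores), matrix, bin_centers)


@dataclass
class UnmixedImage:
    """Per-fluorophore abundance maps plus per-voxel spectral residual."""

    abundances: np.ndarray          # (z, y, x, K)
    residual: np.ndarray            # (z, y, x) RMS spectral residual
    fluorophores: tuple[str, ...]
    voxel_size: tuple[float, float, float]

    def channel(self, fluorophore: str) -> np.ndarray:
        return self.abundances[..., self.fluorophores.index(fluorophore)]


def _check_grid(stack: LambdaStack, refs: ReferenceSpectraSet) -> None:
    if stack.bin_centers.size != refs.bin_centers.size or \
            not np.allclose(stack.bin_centers, refs.bin_centers):
        raise GridMismatchError(
            "stack and reference spectra are on different spectral bin grids")


def extract_reference_spectra(stack: LambdaStack, roi_masks: dict[str, np.ndarray],
                              background_mask: np.ndarray | None = None) -> ReferenceSpectraSet:
    """Build fingerprints from single-stained regions of interest.

    Each ROI mask selects voxels dominated by one fluorophore; the
    fingerprint is the ROI-mean spectrum, optionally background-subtracted
    (median spectrum of ``background_mask``), clipped at zero and
    normalized to unit sum.
    """
    bg = None
    if background_mask is not None:
        if not background_mask.any():
            raise ValueError("background ROI is empty")
        bg = np.median(stack.data[background_mask], axis=0)
    rows, names = [], []
    for name, mask in roi_masks.items():
        if mask.shape != stack.field_shape:
            raise ValueError(f"ROI mask for {name} does not match the field shape")
        if not mask.any():
            raise ValueError(f"ROI for {name} is empty")
        spec = stack.data[mask].mean(axis=0)
        if bg is not None:
            spec = np.clip(spec - bg, 0.0, None)
        if spec.sum() <= 0:
            raise ValueError(f"degenerate (all-zero) spectrum extracted for {name}")
        rows.append(spec)
        names.append(name)
    return ReferenceSpectraSet(tuple(names), np.stack(rows), stack.bin_centers)


def linear_unmix(stack: LambdaStack, refs: ReferenceSpectraSet,
                 nonnegative: bool = True,
                 background_column: bool = False) -> UnmixedImage:
    """Per-voxel linear unmixing of a lambda stack into dye abundances.

    Solves the per-voxel least-squares problem independently at every voxel
    (no spatial coupling, mirroring online instrument unmixing).  With
    ``nonnegative`` (default) abundances are constrained to x >= 0.
    ``background_column`` appends a spectrally flat component to the
    fingerprint matrix to absorb uniform background/autofluorescence; its
    abundance map is returned as an extra ``"background"`` channel.
    """
    _check_grid(stack, refs)
    if background_column:
        flat = np.full((1, refs.bin_centers.size), 1.0)
        refs = ReferenceSpectraSet(refs.fluorophores + ("background",),
                                   np.vstack([refs.matrix, flat]), refs.bin_centers)
    A = refs.matrix                      # K x L
    M = A.T                              # L x K mixing matrix
    spectra = stack.data.reshape(-1, stack.n_bins)
    if nonnegative:
        x = _nnls_batch(M, spectra)
    else:
        x = spectra @ np.linalg.pinv(M).T
    resid = spectra - x @ A
    rms = np.sqrt(np.mean(resid ** 2, axis=1))
    shape = stack.field_shape
    return UnmixedImage(x.reshape(*shape, len(refs.fluorophores)),
                        rms.reshape(shape), refs.fluorophores, stack.voxel_size)


def _nnls_batch(M: np.ndarray, spectra: np.ndarray) -> np.ndarray:
    """Exact NNLS for many right-hand sides, vectorized over voxels.

    With K fluorophores the active set of the NNLS solution is one of 2^K
    support subsets.  For each subset (largest first) the restricted
    unconstrained solution is computed for all still-unsolved voxels in
    one matrix product and accepted where the KKT conditions hold:
    feasibility (x >= 0 on the support) and nonpositive gradient
    (M^T residual <= 0) off the support.  Feasible for small K (64
    subsets at K = 6); any voxel the tolerance leaves unresolved falls
    back to scipy's active-set NNLS.
    """
    n, k = spectra.shape[0], M.shape[1]
    x = np.zeros((n, k))
    scale = np.linalg.norm(spectra, axis=1)
    tol = 1e-9 * np.maximum(scale, 1.0)
    unsolved = np.ones(n, dtype=bool)
    subsets = sorted(range(1, 2 ** k), key=lambda m: -bin(m).count("1"))
    for mask in subsets:
        idx = np.flatnonzero(unsolved)
        if idx.size == 0:
            break
        support = np.array([(mask >> j) & 1 for j in range(k)], dtype=bool)
        Ms = M[:, support]
        xs = spectra[idx] @ np.linalg.pinv(Ms).T
        feas = (xs >= -tol[idx, None]).all(axis=1)
        resid = spectra[idx] - xs @ Ms.T
        grad = resid @ M                                   # (n_i, k)
        opt = (grad[:, ~support] <= tol[idx, None]).all(axis=1) if (~support).any() \
            else np.ones(idx.size, dtype=bool)
        ok = feas & opt
        hit = idx[ok]
        full = np.zeros((hit.size, k))
        full[:, support] = np.clip(xs[ok], 0.0, None)
        x[hit] = full
        unsolved[hit] = False
    # x = 0 is the solution when the gradient at zero is already nonpositive
    idx = np.flatnonzero(unsolved)
    if idx.size:
        zero_ok = (spectra[idx] @ M <= tol[idx, None]).all(axis=1)
        unsolved[idx[zero_ok]] = False
    for i in np.flatnonzero(unsolved):
        x[i], _ = nnls(M, spectra[i])
    return x
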