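"""Ensemble PCA and overlap with the compact-to-extended deformation vector.

The essential degrees of freedom of an aligned conformational ensemble are
the eigenvectors of the 3N x 3N covariance of the flattened frame
coordinates.  Their agreement with an experimentally observed conformational
change is quantified by the correlation cosine: the absolute normalised
inner product between a principal component and the 3N-dimensional
deformation vector joining two superposed conformers.  The root-sum-square
of cosines over a mode subset is the cumulative overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from heatdyn.structures import Ensemble, Residue, Structure
from heatdyn.superpose import kabsch_superpose, _resolve_selection
from heatdyn.gnm import fix_eigenvector_sign

__all__ = [
    "EnsemblePCA", "PCAResults", "DeformationVector", "HistogramSummary",
    "align_ensemble", "deformation_vector", "correlation_cosine",
    "cumulative_overlap", "end_to_end_series", "distance_histogram",
]


def align_ensemble(ensemble: Ensemble, reference: Structure,
                   selection=None) -> Ensemble:
    """Kabsch-superpose every frame onto ``reference`` over ``selection``
    (default all residues), removing rigid-body motion."""
    mask = _resolve_selection(ensemble.residues, selection)
    if not mask.any():
        raise ValueError("empty alignment selection")
    aligned = np.empty_like(ensemble.frames)
    for f in range(ensemble.n_frames):
        t, _ = kabsch_superpose(ensemble.frames[f][mask],
                                reference.coords[mask])
        aligned[f] = t.apply(ensemble.frames[f])
    return Ensemble(ensemble.residues, aligned,
                    frame_spacing=ensemble.frame_spacing,
                    label=ensemble.label)


@dataclass
class DeformationVector:
    """3N-dimensional displacement between two superposed conformers.

    ``vector`` is the raw displacement in Angstrom; ``unit`` its unit-norm
    copy.  ``roster`` is the common residue list the vector is defined over.
    """

    vector: np.ndarray
    roster: list[Residue]
    endpoint_labels: tuple[str, str] = ("from", "to")

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float).ravel()
        if self.vector.size != 3 * len(self.roster):
            raise ValueError("vector length must be 3 x roster size")

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.vector))

    @property
    def unit(self) -> np.ndarray:
        n = self.norm
        if n == 0:
            raise ValueError("zero deformation vector has no direction")
        return self.vector / n


def deformation_vector(from_struct: Structure, to_struct: Structure
                       ) -> DeformationVector:
    """Deformation vector pointing from one conformer to another.

    The target conformer is Kabsch-superposed onto the source over their
    common roster (matched by chain + residue number), so a pure rigid
    motion yields the zero vector.  For PR65 the canonical choice points
    from the compact to the extended crystal structure.
    """
    key = lambda r: (r.chain, r.number)
    from_idx = {key(r): i for i, r in enumerate(from_struct.residues)}
    common = [r for r in to_struct.residues if key(r) in from_idx]
    if len(common) < 3:
        raise ValueError(
            f"common roster too small: {len(common)} residues "
            f"(from has {from_struct.n_residues}, "
            f"to has {to_struct.n_residues})"
        )
    to_idx = {key(r): i for i, r in enumerate(to_struct.residues)}
    fi = np.array([from_idx[key(r)] for r in common])
    ti = np.array([to_idx[key(r)] for r in common])
    t, _ = kabsch_superpose(to_struct.coords[ti], from_struct.coords[fi])
    aligned_to = t.apply(to_struct.coords[ti])
    vec = (aligned_to - from_struct.coords[fi]).ravel()
    roster = [from_struct.residues[i] for i in fi]
    return DeformationVector(
        vec, roster,
        endpoint_labels=(from_struct.label or "from",
                         to_struct.label or "to"))


class EnsemblePCA:
    """PCA of an aligned conformational ensemble.

    Frames must already be superposed (see :func:`align_ensemble`); the
    covariance of the flattened 3N coordinates about their mean is
    diagonalised with a 1/F (population) normalisation.
    """

    def __init__(self, aligned: Ensemble):
        if aligned.n_frames < 2:
            raise ValueError("PCA needs at least 2 frames")
        self.ensemble = aligned

    def fit(self, n_components: int | None = None) -> "PCAResults":
        ens = self.ensemble
        F, N = ens.n_frames, ens.n_residues
        max_comp = min(3 * N, F - 1) if N > 2 else F - 1
        if n_components is None:
            n_components = min(max_comp, 10)
        if not (1 <= n_components <= max_comp):
            raise ValueError(
                f"n_components must be in [1, {max_comp}], "
                f"got {n_components}"
            )
        flat = ens.frames.reshape(F, 3 * N)
        mean = flat.mean(axis=0)
        centered = flat - mean
        # SVD of the centred data matrix; eigenvalues of the 1/F covariance
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        eigvals = (s ** 2) / F
        comps = fix_eigenvector_sign(vt[:n_components].T)
        return PCAResults(
            mean_coords=mean.reshape(N, 3),
            eigenvalues=eigvals[:n_components],
            components=comps,
            total_variance=float(np.sum(centered ** 2) / F),
            roster=ens.residues,
        )


@dataclass
class PCAResults:
    """Principal components of an aligned ensemble.

    ``components`` is 3N x M with unit-norm orthonormal columns PC1..PCM;
    ``eigenvalues`` are the matching variances (Angstrom^2), descending.
    """

    mean_coords: np.ndarray
    eigenvalues: np.ndarray
    components: np.ndarray
    total_variance: float
    roster: list[Residue]

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    def component(self, k: int) -> np.ndarray:
        """1-based principal component ``k`` as a unit 3N-vector."""
        if not (1 <= k <= self.n_components):
            raise ValueError(f"PC{k} not available "
                             f"(have 1..{self.n_components})")
        return self.components[:, k - 1]

    def explained_variance_ratio(self) -> np.ndarray:
        return self.eigenvalues / self.total_variance

    def overlap_row(self, defvec: DeformationVector, n_pcs: int = 5
                    ) -> pd.Series:
        """Correlation cosines of PC1..PCn with a deformation vector plus
        the cumulative PC1-2 overlap, as one labelled row."""
        n_pcs = min(n_pcs, self.n_components)
        vals = {f"PC{k}": correlation_cosine(self.component(k), defvec)
                for k in range(1, n_pcs + 1)}
        if self.n_components >= 2:
            vals["PC1-2"] = cumulative_overlap(
                [self.component(1), self.component(2)], defvec)
        return pd.Series(vals)

    def summary(self) -> str:
        lines = [
            "Ensemble PCA",
            f"  residues: {len(self.roster)}   "
            f"components: {self.n_components}",
            f"  total variance: {self.total_variance:.4f} A^2",
            f"  {'PC':>4} {'eigenvalue':>12} {'var %':>8} {'cum %':>8}",
        ]
        ratio = self.explained_variance_ratio()
        cum = np.cumsum(ratio)
        for k in range(self.n_components):
            lines.append(
                f"  {k + 1:>4} {self.eigenvalues[k]:>12.4f} "
                f"{100 * ratio[k]:>8.2f} {100 * cum[k]:>8.2f}"
            )
        return "\n".join(lines)


def correlation_cosine(pc: np.ndarray, defvec: DeformationVector) -> float:
    """Absolute cosine between a principal component and the unit
    deformation vector (PC sign is arbitrary, so the absolute value is
    taken).  1 means the PC fully describes the conformational change."""
    pc = np.asarray(pc, dtype=float).ravel()
    d = defvec.unit
    if pc.size != d.size:
        raise ValueError(f"dimension mismatch: PC has {pc.size}, "
                         f"deformation vector {d.size}")
    return float(abs(pc @ d) / np.linalg.norm(pc))


def cumulative_overlap(pcs, defvec: DeformationVector) -> float:
    """Root-sum-square of correlation cosines over a set of mutually
    orthonormal components; equals 1 for a complete basis."""
    mat = np.column_stack([np.asarray(p, dtype=float).ravel() for p in pcs])
    gram = mat.T @ mat
    if not np.allclose(gram, np.eye(mat.shape[1]), atol=1e-6):
        raise ValueError("components are not orthonormal "
                         f"(Gram deviation {np.abs(gram - np.eye(mat.shape[1])).max():.2e})")
    d = defvec.unit
    if mat.shape[0] != d.size:
        raise ValueError("dimension mismatch between components and "
                         "deformation vector")
    return float(np.sqrt(np.sum((mat.T @ d) ** 2)))


def end_to_end_series(ensemble: Ensemble, res_a, res_b) -> pd.Series:
    """Per-frame end-to-end C-alpha distance, indexed by time (ns) when the
    ensemble carries a frame spacing, else by frame number."""
    ia = ensemble.index_of(res_a)
    ib = ensemble.index_of(res_b)
    d = np.linalg.norm(ensemble.frames[:, ia] - ensemble.frames[:, ib],
                       axis=1)
    if ensemble.frame_spacing is not None:
        index = pd.Index(
            np.arange(ensemble.n_frames) * ensemble.frame_spacing,
            name="time_ns")
    else:
        index = pd.RangeIndex(ensemble.n_frames, name="frame")
    return pd.Series(d, index=index, name="end_to_end")


@dataclass
class HistogramSummary:
    """Pooled distance-distribution statistics over one or more series."""

    mean: float
    sd: float
    peaks: list[float]
    bin_centers: np.ndarray
    counts: np.ndarray
    per_series_counts: list[np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        total = self.counts.sum()
        return pd.DataFrame({
            "bin_center": self.bin_centers,
            "count": self.counts,
            "density": self.counts / (total * np.diff(
                self.bin_centers).mean() if len(self.bin_centers) > 1
                else 1.0),
        })


def distance_histogram(series_list, bin_width: float = 1.0,
                       smooth_bins: int = 3, merge_bins: int = 2
                       ) -> HistogramSummary:
    """Pooled histogram, mean/SD and peak locations of distance series.

    All series are pooled for the combined statistics (mean, SD with
    1/(n-1), peaks); per-series histograms over the same bins are also
    returned.  Peaks are local maxima of the ``smooth_bins``-bin
    moving-average smoothed counts; peaks closer than ``merge_bins`` bins
    are merged (the higher one kept), and are reported as bin centers.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    series_list = [np.asarray(s, dtype=float).ravel() for s in
                   (series_list if isinstance(series_list, (list, tuple))
                    else [series_list])]
    if not series_list or any(s.size == 0 for s in series_list):
        raise ValueError("need at least one nonempty series")
    pooled = np.concatenate(series_list)
    lo = np.floor(pooled.min() / bin_width) * bin_width
    hi = np.ceil(pooled.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin_width])
    counts, _ = np.histogram(pooled, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    per_series = [np.histogram(s, bins=edges)[0] for s in series_list]

    if len(counts) >= smooth_bins:
        kernel = np.ones(smooth_bins) / smooth_bins
        smoothed = np.convolve(counts, kernel, mode="same")
    else:
        smoothed = counts.astype(float)
    peak_idx = [i for i in range(len(smoothed))
                if smoothed[i] > 0
                and (i == 0 or smoothed[i] >= smoothed[i - 1])
                and (i == len(smoothed) - 1 or smoothed[i] > smoothed[i + 1])]
    # merge peaks closer than merge_bins, keeping the higher
    merged: list[int] = []
    for i in sorted(peak_idx, key=lambda i: -smoothed[i]):
        if all(abs(i - j) > merge_bins for j in merged):
            merged.append(i)
    peaks = sorted(float(centers[i]) for i in merged)

    sd = float(np.std(pooled, ddof=1)) if pooled.size > 1 else 0.0
    return HistogramSummary(
        mean=float(pooled.mean()), sd=sd, peaks=peaks,
        bin_centers=centers, counts=counts, per_series_counts=per_series)
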