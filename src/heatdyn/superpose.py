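"""Rigid-body superposition and fluctuation statistics.

Implements weighted Kabsch superposition (with the proper-rotation
correction), plain RMSD, per-residue RMSF over an aligned ensemble, and
per-section internal RMSD, the statistic obtained by superposing on a
section alone so that only its internal deformation remains.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from heatdyn.structures import Ensemble, Residue, Structure

__all__ = [
    "RigidTransform", "SectionDefinition", "kabsch_superpose", "rmsd",
    "ensemble_rmsf", "internal_rmsd",
]


@dataclass
class RigidTransform:
    """Proper rigid-body motion ``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3),
                           atol=1e-9):
            raise ValueError("rotation is not orthogonal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-9):
            raise ValueError("rotation is improper (det != +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T,
                              -self.rotation.T @ self.translation)


@dataclass
class SectionDefinition:
    """A named set of inclusive residue-number intervals, e.g. the
    N-terminal repeats 1-2 of a solenoid.

    ``ranges`` is a list of ``(first, last)`` author residue numbers;
    ``chain`` optionally restricts to one chain.
    """

    name: str
    ranges: list[tuple[int, int]]
    chain: str | None = None

    def __post_init__(self) -> None:
        if not self.ranges:
            raise ValueError(f"section {self.name!r} has no ranges")
        for lo, hi in self.ranges:
            if hi < lo:
                raise ValueError(
                    f"section {self.name!r}: empty range ({lo}, {hi})"
                )

    def mask(self, residues: Sequence[Residue]) -> np.ndarray:
        """Boolean roster mask of the residues belonging to this section."""
        out = np.zeros(len(residues), dtype=bool)
        for i, r in enumerate(residues):
            if self.chain is not None and r.chain != self.chain:
                continue
            out[i] = any(lo <= r.number <= hi for lo, hi in self.ranges)
        return out


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation between two coordinate sets (no
    superposition; compose with :func:`kabsch_superpose` when needed)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate shapes differ: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     weights: np.ndarray | None = None
                     ) -> tuple[RigidTransform, float]:
    """Optimal weighted rigid superposition of ``mobile`` onto ``reference``.

    Returns the proper rigid transform minimising the weighted RMSD and the
    RMSD achieved after applying it (unweighted RMSD when ``weights`` is
    None).  Reflections are corrected to guarantee ``det(R) = +1``.

    Raises
    ------
    ValueError
        On shape mismatch, fewer than 3 points, or degenerate (collinear or
        coincident) reference geometry for which the rotation is not
        unique.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(
            f"coordinate shapes differ: {mobile.shape} vs {reference.shape}"
        )
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points to superpose")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be a nonnegative length-N vector "
                             "with positive sum")
        w = w / w.sum()

    mob_c = mobile - w @ mobile
    ref_c = reference - w @ reference
    # degenerate geometry: points (weighted) span < 2 dimensions
    if np.linalg.matrix_rank(ref_c * w[:, None], tol=1e-9) < 2:
        raise ValueError("degenerate geometry (collinear or coincident "
                         "points): rotation not unique")
    h = (mob_c * w[:, None]).T @ ref_c
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = (w @ reference) - rotation @ (w @ mobile)
    transform = RigidTransform(rotation, translation)
    return transform, rmsd(transform.apply(mobile), reference)


def _resolve_selection(residues: Sequence[Residue], selection) -> np.ndarray:
    """Turn a selection (None, boolean mask, index array, or
    SectionDefinition) into a boolean roster mask."""
    n = len(residues)
    if selection is None:
        return np.ones(n, dtype=bool)
    if isinstance(selection, SectionDefinition):
        return selection.mask(residues)
    sel = np.asarray(selection)
    if sel.dtype == bool:
        if sel.shape != (n,):
            raise ValueError("boolean selection has wrong length")
        return sel
    mask = np.zeros(n, dtype=bool)
    mask[sel.astype(int)] = True
    return mask


def ensemble_rmsf(ensemble: Ensemble, reference: Structure,
                  align_on=None) -> pd.Series:
    """Per-residue root-mean-square fluctuation of an aligned ensemble.

    Every frame is Kabsch-superposed onto ``reference`` over the
    ``align_on`` selection (default: all residues); fluctuations are then
    measured about the post-alignment ensemble mean position, the standard
    RMSF convention.

    Returns a Series indexed by ``(chain, residue number)``.
    """
    if ensemble.n_residues != reference.n_residues:
        raise ValueError("ensemble and reference rosters differ in size")
    mask = _resolve_selection(ensemble.residues, align_on)
    if not mask.any():
        raise ValueError("empty alignment selection")
    aligned = np.empty_like(ensemble.frames)
    for f in range(ensemble.n_frames):
        t, _ = kabsch_superpose(ensemble.frames[f][mask],
                                reference.coords[mask])
        aligned[f] = t.apply(ensemble.frames[f])
    mean = aligned.mean(axis=0)
    fluct = np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0))
    index = pd.MultiIndex.from_tuples(
        [(r.chain, r.number) for r in ensemble.residues],
        names=["chain", "residue"])
    return pd.Series(fluct, index=index, name="rmsf")


def internal_rmsd(frame: Structure, reference: Structure,
                  section: SectionDefinition) -> float:
    """RMSD of a section after superposing on that section alone.

    Superposition over only the section's residues removes the section's
    rigid-body motion, so the result measures internal deformation rather
    than displacement in space.
    """
    mask_f = section.mask(frame.residues)
    mask_r = section.mask(reference.residues)
    if mask_f.sum() == 0 or mask_r.sum() == 0:
        raise ValueError(f"section {section.name!r} resolves to no residues")
    if mask_f.sum() != mask_r.sum():
        raise ValueError(
            f"section {section.name!r} resolves to different residue counts "
            f"in frame ({mask_f.sum()}) and reference ({mask_r.sum()})"
        )
    _, value = kabsch_superpose(frame.coords[mask_f],
                                reference.coords[mask_r])
    return value
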