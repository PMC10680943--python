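"""Gaussian network model (GNM) and hinge-site detection.

The GNM represents a protein as an elastic network over C-alpha atoms: any
pair within a distance cutoff is joined by a spring of uniform constant
``gamma``.  The network topology is encoded in the Kirchhoff (graph
Laplacian) matrix; the eigenvectors belonging to the smallest nonzero
eigenvalues are the slowest, most collective mode shapes.  Residues at
zero-crossovers of a slow mode shape move minimally and act as global
hinges between anticorrelated substructures.

The model follows the statsmodels convention: build a
:class:`GaussianNetworkModel` from a :class:`~heatdyn.structures.Structure`,
call :meth:`~GaussianNetworkModel.fit`, and inspect the returned
:class:`GNMResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from heatdyn.structures import Residue, Structure

__all__ = [
    "GaussianNetworkModel", "GNMResults", "HingeSet",
    "build_kirchhoff", "fix_eigenvector_sign",
]

DEFAULT_CUTOFF = 10.0  # Angstrom; standard GNM contact cutoff
DEFAULT_BAND = 0.0025  # |mode shape| band defining in-band hinge residues
_ZERO_EIG_TOL = 1e-8


def build_kirchhoff(structure: Structure, cutoff: float = DEFAULT_CUTOFF,
                    gamma: float = 1.0) -> np.ndarray:
    """Kirchhoff (connectivity) matrix of the C-alpha contact network.

    ``K[i, j] = -gamma`` when ``0 < d_ij <= cutoff`` and 0 otherwise;
    diagonal entries make every row sum to zero.

    Raises
    ------
    ValueError
        If ``cutoff <= 0`` or two C-alpha positions coincide (degenerate
        geometry).
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    d = pdist(structure.coords)
    if np.any(d == 0.0):
        raise ValueError("coincident C-alpha pair (zero distance): "
                         "degenerate geometry")
    dmat = squareform(d)
    contact = (dmat <= cutoff)
    np.fill_diagonal(contact, False)
    k = np.where(contact, -float(gamma), 0.0)
    np.fill_diagonal(k, -k.sum(axis=1))
    return k


def fix_eigenvector_sign(v: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: the component of largest magnitude is
    made positive.  Applied column-wise for 2-D input."""
    v = np.asarray(v)
    if v.ndim == 1:
        return v if v[np.argmax(np.abs(v))] >= 0 else -v
    out = v.copy()
    idx = np.argmax(np.abs(out), axis=0)
    signs = np.sign(out[idx, np.arange(out.shape[1])])
    signs[signs == 0] = 1.0
    return out * signs


@dataclass
class HingeSet:
    """Hinge annotation for one GNM mode.

    ``hinge_residues`` contains every residue whose mode-shape component
    lies within ``band`` of zero, plus both flanking residues of any sign
    crossover that has no in-band member.  ``crossovers`` lists the
    sequence-adjacent roster pairs where the mode shape changes sign.
    """

    mode_index: int
    hinge_residues: list[Residue]
    band: float
    crossovers: list[tuple[Residue, Residue]]
    in_band: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.hinge_residues)


class GaussianNetworkModel:
    """GNM over a single conformer.

    Parameters
    ----------
    structure : Structure
        C-alpha conformer.
    cutoff : float
        Contact cutoff in Angstrom (default 10.0, the standard GNM choice).
    gamma : float
        Uniform spring constant setting the eigenvalue scale (default 1.0).
    """

    def __init__(self, structure: Structure, cutoff: float = DEFAULT_CUTOFF,
                 gamma: float = 1.0):
        self.structure = structure
        self.cutoff = float(cutoff)
        self.gamma = float(gamma)
        self.kirchhoff = build_kirchhoff(structure, cutoff, gamma)

    def fit(self, n_modes: int | None = None) -> "GNMResults":
        """Diagonalise the Kirchhoff matrix and return the slow modes.

        The single zero eigenvalue of a connected network (rigid-body
        translation along the mode coordinate) is discarded; modes are
        numbered from 1 in ascending eigenvalue order.

        Raises
        ------
        ValueError
            If the contact graph is disconnected (more than one zero
            eigenvalue); the message names the number of components.
        """
        n = self.kirchhoff.shape[0]
        if n_modes is None:
            n_modes = n - 1
        if not (1 <= n_modes <= n - 1):
            raise ValueError(f"n_modes must be in [1, {n - 1}], "
                             f"got {n_modes}")
        adjacency = (self.kirchhoff != 0) & ~np.eye(n, dtype=bool)
        n_comp, _ = connected_components(adjacency, directed=False)
        if n_comp > 1:
            raise ValueError(
                f"contact graph is disconnected ({n_comp} components); "
                f"increase the cutoff"
            )
        evals, evecs = eigh(self.kirchhoff)
        if abs(evals[0]) > _ZERO_EIG_TOL * max(self.gamma, 1.0):
            warnings.warn("smallest eigenvalue not numerically zero: "
                          f"{evals[0]:g}")
        evals = evals[1:n_modes + 1]
        evecs = fix_eigenvector_sign(evecs[:, 1:n_modes + 1])
        return GNMResults(self, evals, evecs)


class GNMResults:
    """Eigenvalues, mode shapes and hinge annotations of a fitted GNM.

    Attributes
    ----------
    eigenvalues : (M,) array
        Ascending nonzero eigenvalues, in units of ``gamma``.
    eigenvectors : (N, M) array
        Unit-norm mode shapes; column ``k`` is mode ``k+1``.
    """

    def __init__(self, model: GaussianNetworkModel, eigenvalues: np.ndarray,
                 eigenvectors: np.ndarray):
        self.model = model
        self.eigenvalues = np.asarray(eigenvalues, dtype=float)
        self.eigenvectors = np.asarray(eigenvectors, dtype=float)

    @property
    def structure(self) -> Structure:
        return self.model.structure

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    def mode_shape(self, mode_index: int) -> np.ndarray:
        """Mode shape of 1-based ``mode_index`` (zero mode excluded)."""
        if not (1 <= mode_index <= self.n_modes):
            raise ValueError(
                f"mode {mode_index} not available (have 1..{self.n_modes})"
            )
        return self.eigenvectors[:, mode_index - 1]

    def detect_hinges(self, mode_index: int,
                      band: float = DEFAULT_BAND) -> HingeSet:
        """Hinges of one mode: in-band residues plus crossover flanks.

        A crossover is a sequence-adjacent pair of roster residues whose
        mode-shape components have non-positive product.  When neither
        member of a crossover lies within the band, both flanking residues
        are reported (the conservative superset: the true pivot lies
        between them).
        """
        if band < 0:
            raise ValueError("band must be nonnegative")
        v = self.mode_shape(mode_index)
        roster = self.structure.residues
        in_band_mask = np.abs(v) <= band
        hinges: dict[int, None] = {}  # insertion-ordered set of indices
        crossovers = []
        for i in range(len(v) - 1):
            if v[i] * v[i + 1] <= 0:
                crossovers.append((roster[i], roster[i + 1]))
                if not (in_band_mask[i] or in_band_mask[i + 1]):
                    hinges[i] = None
                    hinges[i + 1] = None
        for i in np.flatnonzero(in_band_mask):
            hinges[int(i)] = None
        hinge_residues = [roster[i] for i in sorted(hinges)]
        return HingeSet(
            mode_index=mode_index,
            hinge_residues=hinge_residues,
            band=band,
            crossovers=crossovers,
            in_band=[roster[int(i)] for i in np.flatnonzero(in_band_mask)],
        )

    def multi_mode_hinges(self, modes, band: float = DEFAULT_BAND
                          ) -> dict[int, HingeSet]:
        """Hinge sets for several modes, keyed by mode index.

        Duplicate mode indices are deduplicated with a warning; per-mode
        provenance is preserved in the returned mapping.
        """
        seen = []
        for m in modes:
            if m in seen:
                warnings.warn(f"duplicate mode index {m} ignored")
            else:
                seen.append(m)
        return {m: self.detect_hinges(m, band) for m in seen}

    def hinge_table(self, modes=None, band: float = DEFAULT_BAND
                    ) -> pd.DataFrame:
        """Tidy per-residue hinge report across modes.

        Columns: mode, chain, residue number, residue name, mode-shape
        value, in_band flag, crossover flag.
        """
        if modes is None:
            modes = range(1, self.n_modes + 1)
        rows = []
        for m, hs in self.multi_mode_hinges(modes, band).items():
            v = self.mode_shape(m)
            cross_members = {r for pair in hs.crossovers for r in pair}
            in_band = set(hs.in_band)
            for r in hs.hinge_residues:
                idx = self.structure.index_of((r.chain, r.number))
                rows.append({
                    "mode": m, "chain": r.chain, "residue": r.number,
                    "name": r.name, "shape_value": v[idx],
                    "in_band": r in in_band,
                    "crossover": r in cross_members,
                })
        return pd.DataFrame(
            rows, columns=["mode", "chain", "residue", "name",
                           "shape_value", "in_band", "crossover"])

    def summary(self, modes=None, band: float = DEFAULT_BAND) -> str:
        """Human-readable report of eigenvalues and hinge counts."""
        if modes is None:
            modes = range(1, min(6, self.n_modes) + 1)
        lines = [
            "Gaussian network model",
            f"  residues: {self.structure.n_residues}   "
            f"cutoff: {self.model.cutoff:g} A   gamma: {self.model.gamma:g}",
            f"  modes retained: {self.n_modes}",
            f"  {'mode':>4} {'eigenvalue':>12} {'hinges':>7} "
            f"{'crossovers':>11}",
        ]
        for m in modes:
            hs = self.detect_hinges(m, band)
            lines.append(
                f"  {m:>4} {self.eigenvalues[m - 1]:>12.6f} "
                f"{len(hs):>7d} {len(hs.crossovers):>11d}"
            )
        return "\n".join(lines)
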