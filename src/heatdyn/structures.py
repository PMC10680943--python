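"""Conformers and conformational ensembles at C-alpha resolution.

The package models proteins as ordered lists of residues with one C-alpha
coordinate each.  Two containers are provided: :class:`Structure` (one
conformer) and :class:`Ensemble` (F conformers sharing one residue roster).
PDB reading/writing goes through :mod:`biotite`; a plain whitespace
trajectory dialect (one-line ``F N`` header, then F blocks of N ``x y z``
rows) covers the case where trajectories arrive as bare numbers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

logger = logging.getLogger(__name__)

__all__ = [
    "Residue", "Structure", "Ensemble", "read_pdb_calpha",
    "read_plain_matrix", "write_ensemble", "end_to_end_distance",
    "resolve_selector",
]


class Residue(NamedTuple):
    """Identity of one residue: author chain id, author number, name."""

    chain: str
    number: int
    name: str = ""
    icode: str = ""


@dataclass
class Structure:
    """A single conformer: an ordered residue roster plus C-alpha coordinates.

    Parameters
    ----------
    residues : sequence of Residue
        Ordered roster; residue numbers must be unique within a chain.
    coords : (N, 3) float array
        One C-alpha position per roster entry, in Angstrom.
    label : str
        Free-text identifier (e.g. a PDB id).
    """

    residues: list[Residue]
    coords: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.residues = [Residue(*r) for r in self.residues]
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.residues)
        if n < 2:
            raise ValueError(f"a Structure needs at least 2 residues, got {n}")
        if self.coords.shape != (n, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"{n} residues"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values")
        seen = set()
        for r in self.residues:
            key = (r.chain, r.number, r.icode)
            if key in seen:
                raise ValueError(f"duplicate residue {key} in roster")
            seen.add(key)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def index_of(self, selector) -> int:
        """Resolve a residue selector to a roster index (see
        :func:`resolve_selector`)."""
        return resolve_selector(self.residues, selector)

    def select(self, numbers: Sequence[int] | None = None,
               chain: str | None = None) -> np.ndarray:
        """Boolean mask over the roster for a residue-number set and/or
        chain."""
        mask = np.ones(self.n_residues, dtype=bool)
        if chain is not None:
            mask &= np.array([r.chain == chain for r in self.residues])
        if numbers is not None:
            wanted = set(int(x) for x in numbers)
            mask &= np.array([r.number in wanted for r in self.residues])
        return mask


@dataclass
class Ensemble:
    """F conformers over one shared residue roster.

    ``frame_spacing`` is the time between consecutive frames in ns (or
    ``None`` when the frames are not a time series).
    """

    residues: list[Residue]
    frames: np.ndarray
    frame_spacing: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.residues = [Residue(*r) for r in self.residues]
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError(
                f"frames must be (F, N, 3), got {self.frames.shape}"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("an Ensemble needs at least one frame")
        if self.frames.shape[1] != len(self.residues):
            raise ValueError(
                f"frame width {self.frames.shape[1]} does not match roster "
                f"size {len(self.residues)}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_residues(self) -> int:
        return self.frames.shape[1]

    def frame(self, i: int) -> Structure:
        """Extract frame ``i`` as a Structure."""
        return Structure(self.residues, self.frames[i],
                         label=f"{self.label}[{i}]")

    def index_of(self, selector) -> int:
        return resolve_selector(self.residues, selector)


def resolve_selector(residues: Sequence[Residue], selector) -> int:
    """Resolve a residue selector to a unique roster index.

    Accepted selector forms:

    * ``29`` — author residue number, any chain;
    * ``("A", 29)`` — chain + number;
    * ``("A", 29, "ASN")`` — additionally asserts the residue name and
      fails loudly on mismatch;
    * a :class:`Residue`.

    Raises
    ------
    KeyError
        If the selector matches zero or more than one residue (the message
        carries the match count).
    ValueError
        If a residue-name assertion fails.
    """
    if isinstance(selector, Residue):
        selector = (selector.chain, selector.number,
                    selector.name) if selector.name else (
            selector.chain, selector.number)
    want_name = None
    if isinstance(selector, (int, np.integer)):
        matches = [i for i, r in enumerate(residues)
                   if r.number == int(selector)]
    elif isinstance(selector, tuple) and len(selector) in (2, 3):
        chain, number = selector[0], int(selector[1])
        want_name = selector[2] if len(selector) == 3 else None
        matches = [i for i, r in enumerate(residues)
                   if r.chain == chain and r.number == number]
    else:
        raise TypeError(f"unsupported residue selector: {selector!r}")
    if len(matches) != 1:
        raise KeyError(
            f"selector {selector!r} matched {len(matches)} residues "
            f"(need exactly 1)"
        )
    idx = matches[0]
    if want_name is not None and residues[idx].name != want_name:
        raise ValueError(
            f"residue name assertion failed for {selector!r}: roster has "
            f"{residues[idx].name!r}"
        )
    return idx


def _roster_from_atoms(atoms) -> list[Residue]:
    return [
        Residue(str(c), int(n), str(rn), str(ic))
        for c, n, rn, ic in zip(
            atoms.chain_id, atoms.res_id, atoms.res_name, atoms.ins_code
        )
    ]


def read_pdb_calpha(path, chain: str | None = None,
                    model: int | None = 1) -> Structure | Ensemble:
    """Read C-alpha coordinates from a PDB file.

    Parameters
    ----------
    path : path-like
        PDB file with ATOM records.
    chain : str or None
        Author chain id to keep; ``None`` keeps all chains.
    model : int or None
        1-based model index; ``None`` reads all models and returns an
        :class:`Ensemble` (roster taken from the first model; PDB multi-model
        files share one roster by construction).

    Notes
    -----
    Alternate locations are resolved to the highest-occupancy (then
    first-listed) conformer.  Residues lacking a C-alpha are skipped with a
    logged warning; their identities are collected on the returned object as
    ``skipped_residues``.
    """
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if model is not None and not (1 <= model <= n_models):
        raise ValueError(
            f"model {model} not present; file has models 1..{n_models}"
        )
    atoms = pdb.get_structure(model=model, altloc="occupancy")
    # stack vs array: model=None gives an AtomArrayStack
    template = atoms[0] if model is None else atoms

    chains_present = sorted(set(template.chain_id))
    if chain is not None:
        keep = template.chain_id == chain
        if not np.any(keep):
            raise ValueError(
                f"chain {chain!r} not found; available chains: "
                f"{set(chains_present)}"
            )
        atoms = atoms[:, keep] if model is None else atoms[keep]
        template = atoms[0] if model is None else atoms

    skipped: list[Residue] = []
    ca_mask = np.zeros(template.array_length(), dtype=bool)
    for start, stop in zip(*_residue_slices(template)):
        names = template.atom_name[start:stop]
        hits = np.flatnonzero(names == "CA")
        if hits.size == 0:
            skipped.append(Residue(
                str(template.chain_id[start]), int(template.res_id[start]),
                str(template.res_name[start]), str(template.ins_code[start]),
            ))
            continue
        ca_mask[start + hits[0]] = True
    if skipped:
        logger.warning(
            "%d residues lack a C-alpha and were skipped: %s",
            len(skipped), skipped[:5],
        )

    atoms = atoms[:, ca_mask] if model is None else atoms[ca_mask]
    template = atoms[0] if model is None else atoms
    order = _roster_sort_order(template)
    atoms = atoms[:, order] if model is None else atoms[order]
    template = atoms[0] if model is None else atoms
    roster = _roster_from_atoms(template)

    label = Path(str(path)).stem
    if model is None:
        out: Structure | Ensemble = Ensemble(
            roster, np.asarray(atoms.coord, dtype=float), label=label)
    else:
        out = Structure(roster, np.asarray(atoms.coord, dtype=float),
                        label=label)
    out.skipped_residues = skipped  # type: ignore[attr-defined]
    return out


def _residue_slices(atoms):
    starts = struc.get_residue_starts(atoms)
    stops = np.append(starts[1:], atoms.array_length())
    return starts, stops


def _roster_sort_order(atoms) -> np.ndarray:
    keys = list(zip(atoms.chain_id, atoms.res_id, atoms.ins_code))
    return np.array(sorted(range(len(keys)), key=lambda i: keys[i]),
                    dtype=int)


def write_ensemble(ensemble: Ensemble, path, format: str = "pdb") -> None:
    """Write an ensemble as a multi-model PDB or the plain-matrix dialect.

    The plain-matrix dialect is a one-line header ``F N`` followed by F
    blocks of N whitespace-separated ``x y z`` rows; it round-trips through
    :func:`read_plain_matrix`.
    """
    if format == "pdb":
        frames = []
        for f in range(ensemble.n_frames):
            arr = struc.AtomArray(ensemble.n_residues)
            arr.coord = ensemble.frames[f]
            arr.chain_id = np.array([r.chain for r in ensemble.residues])
            arr.res_id = np.array([r.number for r in ensemble.residues])
            arr.res_name = np.array([r.name or "GLY"
                                     for r in ensemble.residues])
            arr.ins_code = np.array([r.icode for r in ensemble.residues])
            arr.atom_name = np.full(ensemble.n_residues, "CA")
            arr.element = np.full(ensemble.n_residues, "C")
            arr.hetero = np.zeros(ensemble.n_residues, dtype=bool)
            frames.append(arr)
        stack = struc.stack(frames)
        pdb = PDBFile()
        pdb.set_structure(stack)
        pdb.write(str(path))
    elif format == "matrix":
        F, N = ensemble.n_frames, ensemble.n_residues
        with open(path, "w") as fh:
            fh.write(f"{F} {N}\n")
            for f in range(F):
                for row in ensemble.frames[f]:
                    fh.write(f"{row[0]:.6f} {row[1]:.6f} {row[2]:.6f}\n")
    else:
        raise ValueError(f"unknown format {format!r} (use 'pdb' or 'matrix')")


def read_plain_matrix(path, residues: Sequence[Residue] | None = None,
                      frame_spacing: float | None = None,
                      label: str = "") -> Ensemble:
    """Read the plain-matrix trajectory dialect written by
    :func:`write_ensemble`.

    When no roster is supplied, residues are synthesised as chain A,
    numbers 1..N.
    """
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError("plain-matrix header must be 'F N'")
        F, N = int(header[0]), int(header[1])
        data = np.loadtxt(fh)
    if data.shape != (F * N, 3):
        raise ValueError(
            f"expected {F * N} coordinate rows of 3, got {data.shape}"
        )
    if residues is None:
        residues = [Residue("A", i + 1, "GLY") for i in range(N)]
    return Ensemble(list(residues), data.reshape(F, N, 3),
                    frame_spacing=frame_spacing,
                    label=label or Path(str(path)).stem)


def end_to_end_distance(structure: Structure, res_a, res_b) -> float:
    """Euclidean C-alpha/C-alpha distance between two residues, in Angstrom.

    For PR65 the conventional end-to-end pair is N29 and F577; the compact
    and extended crystal conformers sit at 47.7 and 76.3 Angstrom
    respectively.
    """
    ia = structure.index_of(res_a)
    ib = structure.index_of(res_b)
    return float(np.linalg.norm(structure.coords[ia] - structure.coords[ib]))
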