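"""Seeded generators producing every pipeline input with known ground truth.

Real HEAT-repeat trajectories and trap recordings are rarely shareable, so
the package ships generators whose outputs have planted, recoverable
parameters:

* :func:`make_solenoid_pair` — a compact/extended pair of helical bead
  solenoids emulating the 15-repeat PR65 scaffold, with the exact planted
  deformation vector between them;
* :func:`make_ensemble` — Gaussian conformational ensembles whose dominant
  variance lies along a planted deformation direction, with isotropic
  orthogonal noise, optional drift and an optional two-centre (bimodal)
  mode for split-population behaviour;
* :func:`make_ou_trace` — trap transmission traces: flat pre-trap baseline,
  a discrete trapping step, then an exactly-discretised Ornstein-Uhlenbeck
  process with known corner frequency and stationary SD plus a white
  detector noise floor;
* :func:`table1_fixture` / :func:`table2_fixture` — the published
  per-mutation score/measurement tables, shipped as TSV.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from heatdyn.structures import Ensemble, Residue, Structure
from heatdyn.pca import DeformationVector, deformation_vector

__all__ = [
    "SolenoidSpec", "EnsembleSpec", "TraceSpec", "make_solenoid_pair",
    "make_ensemble", "make_ou_trace", "table1_fixture", "table2_fixture",
]


@dataclass
class SolenoidSpec:
    """Geometry of a toy helical-solenoid conformer pair.

    Beads are placed on a helix of given ``radius`` (Angstrom) advancing by
    ``rise_per_repeat`` per repeat and turning by ``twist_per_repeat``
    degrees per repeat; the extended conformer scales the rise by
    ``extension_factor``.  Defaults mimic a 15-repeat, 4-beads-per-repeat
    PR65-like scaffold.
    """

    n_repeats: int = 15
    beads_per_repeat: int = 4
    rise_per_repeat: float = 10.0
    radius: float = 15.0
    twist_per_repeat: float = 25.0
    extension_factor: float = 1.6

    def __post_init__(self) -> None:
        if self.n_repeats < 2:
            raise ValueError("need at least 2 repeats")
        if self.beads_per_repeat < 1:
            raise ValueError("need at least 1 bead per repeat")
        if self.extension_factor < 1:
            raise ValueError("extension_factor must be >= 1")
        if self.radius <= 0 or self.rise_per_repeat <= 0:
            raise ValueError("radius and rise must be positive")

    @property
    def n_beads(self) -> int:
        return self.n_repeats * self.beads_per_repeat


@dataclass
class EnsembleSpec:
    """Planted-mode ensemble parameters.

    ``mode_amplitude`` is the SD (Angstrom) of frame displacements along
    the planted deformation direction; ``noise_amplitude`` the per-
    coordinate SD of the isotropic component orthogonal to it.  ``drift``
    optionally adds a linear trend ``(start, end)`` (Angstrom along the
    mode) across frames; ``centers`` optionally splits the population
    between two displacement centres for bimodal sampling.
    """

    n_frames: int = 500
    mode_amplitude: float = 10.0
    noise_amplitude: float = 1.0
    drift: tuple[float, float] | None = None
    centers: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.mode_amplitude < 0 or self.noise_amplitude < 0:
            raise ValueError("amplitudes must be nonnegative")


@dataclass
class TraceSpec:
    """Planted trap-trace parameters (see :func:`make_ou_trace`).

    ``f_c`` is the corner frequency in Hz (mean-reversion rate
    ``theta = 2 pi f_c``); ``stationary_sd`` the stationary SD of the OU
    component in normalised transmission units; ``noise_floor_sd`` the
    white detector noise added everywhere; ``step_fraction`` the relative
    transmission jump at the trapping step.
    """

    f_c: float = 50.0
    stationary_sd: float = 0.005
    noise_floor_sd: float = 0.001
    pre_level: float = 1.0
    step_fraction: float = 0.15
    duration: float = 10.0
    sampling_rate: float = 100_000.0
    step_time: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("f_c", "stationary_sd", "noise_floor_sd", "pre_level",
                     "step_fraction", "duration", "sampling_rate",
                     "step_time"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.step_time >= self.duration:
            raise ValueError("step_time must fall before the trace ends")
        if self.sampling_rate < 10 * self.f_c:
            raise ValueError(
                f"sampling_rate {self.sampling_rate} undersamples the "
                f"corner frequency {self.f_c} (need >= 10 f_c)"
            )


def make_solenoid_pair(spec: SolenoidSpec = SolenoidSpec()
                       ) -> tuple[Structure, Structure, DeformationVector]:
    """Compact/extended solenoid pair plus the planted deformation vector.

    Both conformers share a roster (chain A, residues 1..N); the extended
    conformer differs only in helical rise, so its end-to-end distance is
    strictly larger.  The planted vector is
    ``deformation_vector(compact, extended)``, i.e. it already accounts
    for the optimal superposition of the two.
    """
    n = spec.n_beads
    k = np.arange(n)
    angle = np.deg2rad(spec.twist_per_repeat) * k / spec.beads_per_repeat
    rise_per_bead = spec.rise_per_repeat / spec.beads_per_repeat

    def helix(rise):
        return np.column_stack([
            spec.radius * np.cos(angle),
            spec.radius * np.sin(angle),
            rise * k,
        ])

    roster = [Residue("A", int(i) + 1, "GLY") for i in k]
    compact = Structure(roster, helix(rise_per_bead), label="solenoid")
    extended = Structure(roster, helix(rise_per_bead *
                                       spec.extension_factor),
                         label="solenoid-extended")
    planted = deformation_vector(compact, extended)
    return compact, extended, planted


def make_ensemble(compact: Structure, planted: DeformationVector,
                  spec: EnsembleSpec = EnsembleSpec()) -> Ensemble:
    """Gaussian ensemble about ``compact`` with a planted dominant mode.

    Frame k is ``compact + a_k * d_hat + eps_k`` with
    ``a_k ~ N(mu_k, mode_amplitude)`` and ``eps_k`` isotropic Gaussian
    noise projected orthogonal to the unit planted direction ``d_hat``.
    ``mu_k`` follows the drift/centres options of :class:`EnsembleSpec`.
    """
    degenerate = planted.norm < 1e-9  # numerically zero direction
    if degenerate and spec.mode_amplitude > 0:
        raise ValueError("cannot plant displacement along a zero "
                         "deformation vector")
    n = compact.n_residues
    if planted.vector.size != 3 * n:
        raise ValueError("planted vector dimension does not match structure")
    rng = np.random.default_rng(spec.seed)
    d_hat = np.zeros(3 * n) if degenerate else planted.unit

    mu = np.zeros(spec.n_frames)
    if spec.drift is not None:
        mu = np.linspace(spec.drift[0], spec.drift[1], spec.n_frames)
    if spec.centers is not None:
        which = rng.integers(0, 2, size=spec.n_frames)
        mu = mu + np.where(which == 0, spec.centers[0], spec.centers[1])

    a = rng.normal(mu, spec.mode_amplitude)
    eps = rng.normal(0.0, spec.noise_amplitude, size=(spec.n_frames, 3 * n))
    if planted.norm > 0:
        eps -= np.outer(eps @ d_hat, d_hat)
    flat = compact.coords.ravel() + np.outer(a, d_hat) + eps
    return Ensemble(compact.residues,
                    flat.reshape(spec.n_frames, n, 3),
                    label=f"{compact.label}-ensemble")


def make_ou_trace(spec: TraceSpec = TraceSpec()
                  ) -> tuple["TweezerTrace", TraceSpec]:
    """Simulated trap transmission trace with planted ground truth.

    Pre-step samples sit at ``pre_level`` plus floor noise; post-step
    samples at ``pre_level * (1 + step_fraction)`` plus an Ornstein-
    Uhlenbeck process using the exact discretisation
    ``x[n+1] = x[n] * exp(-2 pi f_c dt)
    + stationary_sd * sqrt(1 - exp(-4 pi f_c dt)) * xi[n]``
    (initialised from the stationary law), plus floor noise.  Returns the
    trace and the spec echoed back as ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    n_total = int(round(spec.duration * spec.sampling_rate))
    n_pre = int(round(spec.step_time * spec.sampling_rate))
    n_post = n_total - n_pre
    dt = 1.0 / spec.sampling_rate
    decay = np.exp(-2 * np.pi * spec.f_c * dt)

    pre = spec.pre_level + rng.normal(0, spec.noise_floor_sd, n_pre)
    innovations = rng.normal(0.0, 1.0, n_post)
    x0 = rng.normal(0.0, spec.stationary_sd)
    scale = spec.stationary_sd * np.sqrt(1 - decay ** 2)
    # AR(1) recursion via an IIR filter, seeded from the stationary state
    ou, _ = lfilter([scale], [1.0, -decay], innovations, zi=[decay * x0])
    post = (spec.pre_level * (1 + spec.step_fraction) + ou
            + rng.normal(0, spec.noise_floor_sd, n_post))

    from heatdyn.tweezer import TweezerTrace
    trace = TweezerTrace(np.concatenate([pre, post]), spec.sampling_rate,
                         label=f"ou-fc{spec.f_c:g}-seed{spec.seed}")
    return trace, spec


def _load_table(name: str) -> pd.DataFrame:
    with resources.files("heatdyn.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def table1_fixture() -> pd.DataFrame:
    """Published interface mutations with predicted folding-free-energy
    change (kcal/mol) and pathogenicity score; all classify as pathogenic
    under the default cutoffs."""
    return _load_table("table1.tsv")


def table2_fixture() -> pd.DataFrame:
    """Published per-system measurement table for WT and the six hinge
    mutants: pathogenicity, mean/SD end-to-end distance (Angstrom) from
    simulation, and corner frequency (Hz) / normalized RMSD (each
    mean +/- SD) from trap experiments."""
    return _load_table("table2.tsv")
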