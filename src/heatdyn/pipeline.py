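"""Orchestration: per-system reports, mutation triage, cross-modality
correlation.

Joins the structural side (ensemble statistics, PCA overlaps) with the
single-molecule side (corner frequencies, normalized RMSD) by system label,
classifies mutations by pathogenicity score and folding-free-energy change,
and computes the Pearson correlations that tie simulation to experiment.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from heatdyn.structures import Ensemble, Structure
from heatdyn.superpose import SectionDefinition, ensemble_rmsf, internal_rmsd
from heatdyn.pca import (
    EnsemblePCA, align_ensemble, deformation_vector, distance_histogram,
    end_to_end_series,
)
from heatdyn.tweezer import TrapTraceModel, TweezerTrace, read_trace

__all__ = [
    "MutationRecord", "RepeatAnnotation", "SystemReport",
    "classify_mutation", "aggregate_scores", "pearson", "cross_modality",
    "run_structural_report", "run_tweezer_report",
]

PATHOGENICITY_CUTOFF = 0.65   # score above which a substitution is deleterious
DDG_CUTOFF = 1.25             # kcal/mol; boundary of "highly destabilizing"


def classify_mutation(pathogenicity: float, ddg: float | None = None,
                      pathogenicity_cutoff: float = PATHOGENICITY_CUTOFF,
                      ddg_cutoff: float = DDG_CUTOFF) -> str:
    """Triage a mutation by pathogenicity score and folding ddG.

    Group ``a`` (pathogenic) when the score exceeds the cutoff; otherwise
    the non-pathogenic group is split by predicted destabilisation:
    ``b1`` (ddG < 0, not destabilizing), ``b2`` (0 <= ddG < cutoff, mildly
    destabilizing), ``b3`` (ddG >= cutoff, highly destabilizing).  A
    non-pathogenic score with no ddG available yields ``unclassified``.
    """
    if not (0 <= pathogenicity <= 1):
        raise ValueError(
            f"pathogenicity must lie in [0, 1], got {pathogenicity}"
        )
    if pathogenicity > pathogenicity_cutoff:
        return "a"
    if ddg is None or (isinstance(ddg, float) and math.isnan(ddg)):
        return "unclassified"
    if ddg < 0:
        return "b1"
    if ddg < ddg_cutoff:
        return "b2"
    return "b3"


@dataclass
class MutationRecord:
    """One mutation with its predictor scores and triage group."""

    label: str
    pathogenicity: float
    ddg: float | None = None
    group: str = ""

    def __post_init__(self) -> None:
        expected = classify_mutation(self.pathogenicity, self.ddg)
        if not self.group:
            self.group = expected
        elif self.group != expected:
            raise ValueError(
                f"{self.label}: group {self.group!r} inconsistent with "
                f"scores (expected {expected!r})"
            )


@dataclass
class RepeatAnnotation:
    """Residue ranges of the loop0-helix1-loop1-helix2-loop2 motif per
    repeat.

    ``elements`` maps repeat index -> element name -> list of inclusive
    ``(first, last)`` residue-number ranges.  Ranges must not overlap
    within a repeat.
    """

    elements: dict[int, dict[str, list[tuple[int, int]]]]

    def __post_init__(self) -> None:
        for rep, elems in self.elements.items():
            covered: list[tuple[int, int]] = []
            for name, ranges in elems.items():
                for lo, hi in ranges:
                    if hi < lo:
                        raise ValueError(
                            f"repeat {rep} {name}: empty range ({lo},{hi})"
                        )
                    for plo, phi in covered:
                        if lo <= phi and plo <= hi:
                            raise ValueError(
                                f"repeat {rep}: overlapping ranges"
                            )
                    covered.append((lo, hi))

    def repeat_residues(self, rep: int) -> list[int]:
        out = []
        for ranges in self.elements[rep].values():
            for lo, hi in ranges:
                out.extend(range(lo, hi + 1))
        return sorted(out)


def aggregate_scores(per_residue_scores, annotation: RepeatAnnotation
                     ) -> tuple[pd.Series, pd.DataFrame, list[int]]:
    """Mean score per repeat and per structural element.

    ``per_residue_scores`` maps residue number -> score.  Annotated
    residues without a score are excluded from the denominators and
    returned as the missing list; an element left empty after exclusions
    appears as NaN (reported absent, never silently zero).
    """
    scores = dict(per_residue_scores)
    missing: list[int] = []
    repeat_means = {}
    element_rows = []
    for rep in sorted(annotation.elements):
        rep_vals = []
        for elem, ranges in annotation.elements[rep].items():
            vals = []
            for lo, hi in ranges:
                for r in range(lo, hi + 1):
                    if r in scores:
                        vals.append(scores[r])
                    else:
                        missing.append(r)
            element_rows.append({
                "repeat": rep, "element": elem,
                "mean_score": float(np.mean(vals)) if vals else np.nan,
                "n_scored": len(vals),
            })
            rep_vals.extend(vals)
        repeat_means[rep] = (float(np.mean(rep_vals)) if rep_vals
                             else np.nan)
    per_repeat = pd.Series(repeat_means, name="mean_score")
    per_repeat.index.name = "repeat"
    return per_repeat, pd.DataFrame(element_rows), sorted(set(missing))


def pearson(x, y) -> float:
    """Sample Pearson correlation coefficient.

    Requires equal lengths of at least 3 and nonzero variance in both
    inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    return float(stats.pearsonr(x, y).statistic)


def cross_modality(struct_summary: pd.DataFrame,
                   tweezer_summary: pd.DataFrame,
                   pairs: list[tuple[str, str]]) -> pd.DataFrame:
    """Pearson r between simulation-side and experiment-side columns.

    Both frames must be indexed by system label; systems are matched by
    label and each requested (structural column, tweezer column) pair
    yields one row with r and the number of common systems.
    """
    common = struct_summary.index.intersection(tweezer_summary.index)
    if len(common) < 3:
        raise ValueError(
            f"only {len(common)} common systems; need at least 3"
        )
    rows = []
    for sc, tc in pairs:
        r = pearson(struct_summary.loc[common, sc],
                    tweezer_summary.loc[common, tc])
        rows.append({"struct_column": sc, "tweezer_column": tc,
                     "pearson_r": r, "n": len(common)})
    return pd.DataFrame(rows)


@dataclass
class SystemReport:
    """All structural (and optionally tweezer) observables for one system.

    Fields are ``None`` when their inputs were absent — never silently
    zero.
    """

    label: str
    mean_end_to_end: float | None = None
    sd_end_to_end: float | None = None
    histogram_peaks: list[float] | None = None
    rmsf: pd.Series | None = None
    internal_rmsd: dict[str, float] | None = None
    overlap_row: pd.Series | None = None
    corner_frequency_mean: float | None = None
    corner_frequency_sd: float | None = None
    normalized_rmsd_mean: float | None = None
    normalized_rmsd_sd: float | None = None

    def to_row(self) -> pd.Series:
        row = {
            "mean_end_to_end_A": self.mean_end_to_end,
            "sd_end_to_end_A": self.sd_end_to_end,
            "corner_frequency_hz": self.corner_frequency_mean,
            "corner_frequency_sd_hz": self.corner_frequency_sd,
            "normalized_rmsd": self.normalized_rmsd_mean,
            "normalized_rmsd_sd": self.normalized_rmsd_sd,
        }
        if self.overlap_row is not None:
            row.update(self.overlap_row.to_dict())
        return pd.Series(row, name=self.label)


def _write_manifest(output_dir: Path, inputs: dict, seed) -> None:
    from heatdyn import __version__
    blob = json.dumps(inputs, sort_keys=True, default=str).encode()
    manifest = {
        "package": "heatdyn",
        "version": __version__,
        "seed": seed,
        "inputs": inputs,
        "config_hash": hashlib.sha256(blob).hexdigest(),
    }
    (output_dir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str))


def run_structural_report(systems: dict[str, Ensemble],
                          compact: Structure, extended: Structure,
                          end_to_end: tuple = (("A", 1), ("A", 2)),
                          sections: list[SectionDefinition] | None = None,
                          n_pcs: int = 5, bin_width: float = 1.0,
                          output_dir=None, seed=None
                          ) -> dict[str, SystemReport]:
    """Full structural analysis of one or more conformational ensembles.

    For each system: end-to-end distance statistics and histogram peaks,
    per-residue RMSF, per-section internal RMSD averaged over frames, and
    the PCA overlap row (PC1..PCn correlation cosines with the
    compact-to-extended deformation vector plus cumulative PC1-2).
    Deterministic given its inputs; when ``output_dir`` is set, TSV
    outputs and a machine-readable run manifest are written.
    """
    defvec = deformation_vector(compact, extended)
    reports: dict[str, SystemReport] = {}
    for label in sorted(systems):
        ens = systems[label]
        try:
            series = end_to_end_series(ens, *end_to_end)
            hist = distance_histogram([series.to_numpy()],
                                      bin_width=bin_width)
            aligned = align_ensemble(ens, compact)
            n_comp = min(n_pcs, aligned.n_frames - 1, 3 * ens.n_residues)
            pca_res = EnsemblePCA(aligned).fit(n_components=max(n_comp, 2))
            overlap = pca_res.overlap_row(defvec, n_pcs=n_pcs)
            rmsf = ensemble_rmsf(ens, compact)
            internal = None
            if sections:
                internal = {}
                for sec in sections:
                    vals = [internal_rmsd(ens.frame(i), compact, sec)
                            for i in range(ens.n_frames)]
                    internal[sec.name] = float(np.mean(vals))
            reports[label] = SystemReport(
                label=label,
                mean_end_to_end=hist.mean, sd_end_to_end=hist.sd,
                histogram_peaks=hist.peaks, rmsf=rmsf,
                internal_rmsd=internal, overlap_row=overlap)
        except Exception as exc:
            raise RuntimeError(f"system {label!r}: {exc}") from exc

    if output_dir is not None:
        output_dir = Path(output_dir)
        output_dir.mkdir(parents=True, exist_ok=True)
        summary = pd.DataFrame({lbl: r.to_row()
                                for lbl, r in reports.items()}).T
        summary.index.name = "system"
        summary.to_csv(output_dir / "structural_summary.tsv", sep="\t")
        overlap_tbl = pd.DataFrame(
            {lbl: r.overlap_row for lbl, r in reports.items()}).T
        overlap_tbl.index.name = "system"
        overlap_tbl.to_csv(output_dir / "overlap_table.tsv", sep="\t")
        for lbl, r in reports.items():
            r.rmsf.to_csv(output_dir / f"rmsf_{lbl}.tsv", sep="\t")
        _write_manifest(output_dir, {
            "systems": {k: v.label for k, v in systems.items()},
            "end_to_end": end_to_end, "n_pcs": n_pcs,
            "bin_width": bin_width,
            "compact": compact.label, "extended": extended.label,
        }, seed)
    return reports


def run_tweezer_report(traces: dict[str, list], output_dir=None,
                       seed=None, **model_kwargs) -> pd.DataFrame:
    """Aggregate per-trace trap observables to per-system mean +/- SD.

    ``traces`` maps system label -> list of :class:`TweezerTrace` (or
    paths readable by :func:`~heatdyn.tweezer.read_trace`).  Traces whose
    step detection or spectral fit fails are listed in the ``failures``
    column, never silently dropped; a system with no usable trace gets a
    NaN row (explicit empty-summary marker).
    """
    rows = []
    for label in sorted(traces):
        fcs, nrmsds, failures = [], [], []
        for item in traces[label]:
            trace = item if isinstance(item, TweezerTrace) else read_trace(
                item, label=str(item))
            try:
                res = TrapTraceModel(trace, **model_kwargs).fit()
                fcs.append(res.corner_frequency)
                nrmsds.append(res.nrmsd)
            except Exception as exc:
                failures.append(f"{trace.label}: {exc}")
        rows.append({
            "system": label,
            "n_traces": len(fcs),
            "corner_frequency_hz": np.mean(fcs) if fcs else np.nan,
            "corner_frequency_sd_hz": (np.std(fcs, ddof=1)
                                       if len(fcs) > 1 else np.nan),
            "normalized_rmsd": np.mean(nrmsds) if nrmsds else np.nan,
            "normalized_rmsd_sd": (np.std(nrmsds, ddof=1)
                                   if len(nrmsds) > 1 else np.nan),
            "failures": "; ".join(failures),
        })
    out = pd.DataFrame(rows).set_index("system")
    if output_dir is not None:
        output_dir = Path(output_dir)
        output_dir.mkdir(parents=True, exist_ok=True)
        out.to_csv(output_dir / "tweezer_summary.tsv", sep="\t")
        _write_manifest(output_dir, {
            "systems": {k: len(v) for k, v in traces.items()},
            "model_kwargs": model_kwargs,
        }, seed)
    return out
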