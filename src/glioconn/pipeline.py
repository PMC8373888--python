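"""End-to-end orchestration: build -> summarize -> analyze -> report.

``analyze_cohort`` runs the full analysis on in-memory subject bundles;
``run_full_analysis`` is the file-driven variant configured by a
:class:`RunConfig`.  The sequence is: control edge mask -> per-subject EW /
FA / FC matrices -> mask restriction -> hemispheric compartment means ->
lesion relabelling (controls: left/right baseline) -> group-wise outlier
correction -> three MANOVAs (ipsilesional, contralesional and
interhemispheric; dependent variables EW, FA, FC) with univariate follow-ups
and Bonferroni post-hocs -> per-group coherence profiles -> dissociation
summary; optionally repeated on the DMN sub-atlas.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .coherence import coherence_profile, dissociation_summary
from .connectome import (ConnectivityMatrix, EdgeMask, FAEdgeMatrix,
                         RoiTimeSeries, StreamlineCountMatrix,
                         control_edge_mask, edge_weight_matrix, fa_connectivity,
                         fc_matrix, restrict)
from .parcellation import (AtlasDefinition, compartment_codes, default_atlas,
                           dmn_subatlas, load_atlas)
from .stats import anova_oneway, manova_pillai, posthoc_bonferroni
from .summarize import (MODALITIES, SubjectRecord, assemble_cohort_table,
                        hemispheric_means)

logger = logging.getLogger(__name__)

SCOPES = ("whole_brain", "dmn", "both")
COMPARTMENT_VARS = ("ipsi", "contra", "inter")


class PipelineError(RuntimeError):
    """A stage failure, carrying stage and subject context."""


@dataclass
class RunConfig:
    """File paths and analysis knobs for a full run."""

    data_dir: str
    out_dir: str
    atlas_path: str | None = None   # None -> packaged 246-region atlas
    scope: str = "whole_brain"
    alpha: float = 0.05
    coherence_family_size: int = 9
    outlier_sd: float = 2.5

    def __post_init__(self) -> None:
        if self.scope not in SCOPES:
            raise ValueError(f"scope must be one of {SCOPES}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.outlier_sd <= 0:
            raise ValueError("outlier SD threshold must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


@dataclass(frozen=True)
class SubjectData:
    """Raw derivatives for one subject, as read from disk or simulated."""

    record: SubjectRecord
    counts: StreamlineCountMatrix
    fa: FAEdgeMatrix
    timeseries: RoiTimeSeries


def _subject_matrices(data: SubjectData, mask: EdgeMask):
    ew = restrict(edge_weight_matrix(data.counts), mask)
    fa = restrict(fa_connectivity(data.fa, data.counts), mask)
    fc = restrict(fc_matrix(data.timeseries), mask)
    return {"EW": ew, "FA": fa, "FC": fc}


def _edge_counts(mask: EdgeMask, atlas: AtlasDefinition) -> dict:
    codes = compartment_codes(atlas)
    upper = np.triu(np.ones_like(mask.eligible), k=1).astype(bool)
    sel = mask.eligible & upper
    return {
        "intra_left": int((sel & (codes == 0)).sum()),
        "intra_right": int((sel & (codes == 1)).sum()),
        "interhemispheric": int((sel & (codes == 2)).sum()),
    }


def build_summary_table(subject_data, atlas: AtlasDefinition,
                        mask: EdgeMask | None = None,
                        outlier_sd: float = 2.5):
    """Mask, build, restrict and summarize; returns (table, mask, sidecar)."""
    subject_data = list(subject_data)
    if mask is None:
        controls = [d.counts for d in subject_data
                    if d.record.group == "control"]
        if not controls:
            raise PipelineError("stage control_edge_mask: no control subjects")
        mask = control_edge_mask(controls)
    subject_means = {}
    edge_contributions = {}
    for data in subject_data:
        sid = data.record.subject_id
        try:
            matrices = _subject_matrices(data, mask)
            means = {m: hemispheric_means(matrices[m], mask, atlas)
                     for m in MODALITIES}
        except Exception as exc:
            raise PipelineError(
                f"stage summarize, subject {sid!r}: {exc}") from exc
        subject_means[sid] = means
        edge_contributions[sid] = {
            m: {"left": means[m].n_left, "right": means[m].n_right,
                "inter": means[m].n_inter} for m in MODALITIES}
    table, outlier_flags = assemble_cohort_table(
        [d.record for d in subject_data], subject_means, outlier_sd)
    sidecar = {"outlier_flags": outlier_flags,
               "contributing_edges": edge_contributions,
               "mask_edge_counts": _edge_counts(mask, atlas)}
    return table, mask, sidecar


def group_difference_tests(table: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Three MANOVAs (one per compartment) with univariate follow-ups.

    Univariate ANOVAs and Bonferroni post-hocs are computed unconditionally
    but flagged ``gated`` by whether the omnibus multivariate test passed at
    ``alpha``, so hierarchical reporting never hides results.
    """
    labels = table["group"].to_numpy()
    out = {}
    for comp in COMPARTMENT_VARS:
        dvs = [f"{m}_{comp}" for m in MODALITIES]
        manova = manova_pillai(labels, table[dvs].to_numpy(dtype=float))
        gated = bool(manova.p < alpha)
        univariate = {}
        for modality in MODALITIES:
            column = f"{modality}_{comp}"
            anova = anova_oneway(labels, table[column].to_numpy(dtype=float))
            posthoc = posthoc_bonferroni(labels,
                                         table[column].to_numpy(dtype=float))
            univariate[modality] = {"anova": anova, "posthoc": posthoc,
                                    "gated": gated and anova.p < alpha}
        out[comp] = {"manova": manova, "gated": gated,
                     "univariate": univariate}
    return out


def coherence_analysis(table: pd.DataFrame, alpha: float = 0.05,
                       family_size: int = 9) -> dict:
    profiles = [coherence_profile(table, group, alpha, family_size)
                for group in ("control", "IDHmut", "IDHwt")
                if (table["group"] == group).any()]
    return {"profiles": {p.group: p for p in profiles},
            "dissociation": dissociation_summary(profiles)}


def analyze_cohort(subject_data, atlas: AtlasDefinition,
                   scope: str = "whole_brain", alpha: float = 0.05,
                   coherence_family_size: int = 9, outlier_sd: float = 2.5,
                   with_coherence: bool = True) -> dict:
    """Run the complete analysis and return a nested report dict."""
    if scope not in SCOPES:
        raise PipelineError(f"unknown scope {scope!r}")
    subject_data = list(subject_data)
    report: dict = {"n_subjects": len(subject_data),
                    "groups": dict(pd.Series(
                        [d.record.group for d in subject_data])
                        .value_counts().sort_index())}
    table, mask, sidecar = build_summary_table(subject_data, atlas,
                                               outlier_sd=outlier_sd)
    scopes = {}
    if scope in ("whole_brain", "both"):
        block = {"summary_table": table, "sidecar": sidecar,
                 "group_tests": group_difference_tests(table, alpha)}
        if with_coherence:
            block["coherence"] = coherence_analysis(table, alpha,
                                                    coherence_family_size)
        scopes["whole_brain"] = block
    if scope in ("dmn", "both"):
        sub_atlas = dmn_subatlas(atlas)
        idx = np.flatnonzero(atlas.dmn_member)
        sub_mask = EdgeMask(mask.eligible[np.ix_(idx, idx)], mask.provenance)
        sub_data = [SubjectData(
            record=d.record,
            counts=StreamlineCountMatrix(
                d.counts.counts[np.ix_(idx, idx)], d.record.subject_id),
            fa=FAEdgeMatrix(d.fa.fa[np.ix_(idx, idx)], d.record.subject_id),
            timeseries=RoiTimeSeries(d.timeseries.values[:, idx],
                                     d.record.subject_id))
            for d in subject_data]
        sub_table, _, sub_sidecar = build_summary_table(
            sub_data, sub_atlas, mask=sub_mask, outlier_sd=outlier_sd)
        block = {"summary_table": sub_table, "sidecar": sub_sidecar,
                 "group_tests": group_difference_tests(sub_table, alpha)}
        if with_coherence:
            block["coherence"] = coherence_analysis(sub_table, alpha,
                                                    coherence_family_size)
        scopes["dmn"] = block
    report["scopes"] = scopes
    return report


def load_subject_data(data_dir, atlas: AtlasDefinition):
    """Read subjects.csv and the per-subject matrix TSVs from a directory."""
    data_dir = Path(data_dir)
    records = io.read_subjects_csv(data_dir / "subjects.csv")
    r = atlas.n_regions
    out = []
    for record in records:
        sid = record.subject_id
        counts = io.read_matrix_tsv(data_dir / f"{sid}_counts.tsv", r)
        fa = io.read_matrix_tsv(data_dir / f"{sid}_fa.tsv", r)
        ts = io.read_timeseries_tsv(data_dir / f"{sid}_ts.tsv", r)
        out.append(SubjectData(
            record=record,
            counts=StreamlineCountMatrix(np.nan_to_num(counts), sid),
            fa=FAEdgeMatrix(fa, sid),
            timeseries=RoiTimeSeries(ts, sid)))
    return out


def _serialize_block(block: dict) -> dict:
    out = {"group_tests": block["group_tests"],
           "mask_edge_counts": block["sidecar"]["mask_edge_counts"],
           "outlier_flags": block["sidecar"]["outlier_flags"]}
    if "coherence" in block:
        out["coherence"] = {
            "profiles": {g: p.to_frame()
                         for g, p in block["coherence"]["profiles"].items()},
            "dissociation": block["coherence"]["dissociation"],
        }
    return out


def write_report(report: dict, out_dir) -> None:
    """Write CSV result families and the consolidated JSON report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {"n_subjects": report["n_subjects"],
               "groups": report["groups"], "scopes": {}}
    for scope, block in report["scopes"].items():
        prefix = "" if scope == "whole_brain" else f"{scope}_"
        io.write_summary_csv(out_dir / f"{prefix}summary_table.csv",
                             block["summary_table"],
                             sidecar=block["sidecar"],
                             sidecar_path=out_dir / f"{prefix}summary_"
                                                    "sidecar.json")
        manova_rows, anova_rows, posthoc_rows = [], [], []
        for comp, tests in block["group_tests"].items():
            m = tests["manova"]
            manova_rows.append({
                "compartment": comp, "pillai_V": m.pillai_V, "F": m.F,
                "df1": m.df1, "df2": m.df2, "p": m.p,
                "wilks_lambda": m.wilks_lambda})
            for modality, uni in tests["univariate"].items():
                a = uni["anova"]
                anova_rows.append({
                    "compartment": comp, "modality": modality, "F": a.F,
                    "df1": a.df1, "df2": a.df2, "p": a.p,
                    "gated": uni["gated"]})
                for ph in uni["posthoc"]:
                    posthoc_rows.append({
                        "compartment": comp, "modality": modality,
                        "group_a": ph.group_a, "group_b": ph.group_b,
                        "mean_difference": ph.mean_difference, "t": ph.t,
                        "df": ph.df, "p_raw": ph.p_raw,
                        "p_bonferroni": ph.p_bonferroni})
        pd.DataFrame(manova_rows).to_csv(
            out_dir / f"{prefix}manova_results.csv", index=False)
        pd.DataFrame(anova_rows).to_csv(
            out_dir / f"{prefix}anova_results.csv", index=False)
        pd.DataFrame(posthoc_rows).to_csv(
            out_dir / f"{prefix}posthoc_results.csv", index=False)
        if "coherence" in block:
            frames = [p.to_frame()
                      for p in block["coherence"]["profiles"].values()]
            pd.concat(frames, ignore_index=True).to_csv(
                out_dir / f"{prefix}coherence_profile.csv", index=False)
            block["coherence"]["dissociation"].to_csv(
                out_dir / f"{prefix}dissociation_summary.csv", index=False)
        payload["scopes"][scope] = _serialize_block(block)
    io.write_json(out_dir / "report.json", payload)


def run_full_analysis(config: RunConfig) -> dict:
    """File-driven end-to-end run; writes all outputs under out_dir."""
    atlas = (load_atlas(config.atlas_path) if config.atlas_path
             else default_atlas())
    data_path = Path(config.data_dir)
    if (data_path / "atlas.csv").exists() and config.atlas_path is None:
        atlas = load_atlas(data_path / "atlas.csv")
    subject_data = load_subject_data(config.data_dir, atlas)
    report = analyze_cohort(subject_data, atlas, scope=config.scope,
                            alpha=config.alpha,
                            coherence_family_size=config.coherence_family_size,
                            outlier_sd=config.outlier_sd)
    write_report(report, config.out_dir)
    return report


def cohort_to_subject_data(cohort):
    """Adapt simulated bundles to the pipeline's SubjectData records."""
    return [SubjectData(record=b.record, counts=b.counts, fa=b.fa,
                        timeseries=b.timeseries) for b in cohort.bundles]
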