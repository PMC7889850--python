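"""End-to-end orchestration: QC -> distances -> ANOSIM/Mantel -> rarefaction.

``run_compare`` executes the whole comparison from a declarative config
and writes a summary (JSON + text table with significance stars) plus the
per-stage artifacts.  Every stochastic stage takes a seed recorded in the
run manifest, so a summary is reproducible from the manifest alone.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from . import aflp_qc, dissimilarity, inference_stats, rarefaction
from .io_formats import (
    BinaryMarkerMatrix,
    DistanceMatrix,
    GenotypeMatrix,
    SampleMetadata,
    filter_loci_by_missingness,
    read_binary_marker_table,
    read_genotype_table,
    read_sample_metadata,
    write_binary_marker_table,
    write_distance_matrix,
)
from .inference_stats import significance_stars

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"[{stage}] {detail}")
        self.stage = stage


DEFAULT_CONFIG: dict[str, Any] = {
    "aflp": {"table": None, "meta": None},
    "snp": {"table": None, "format": "dosage_table", "meta": None,
            "max_missing": 0.75},
    "qc": {"screen": False, "coverage": 0.90, "indiv_threshold": 0.5,
           "combo_threshold": 0.1, "iterate": False},
    "stats": {"permutations": 9999},
    "rarefaction": {"enabled": False, "step": 50, "reps": 50,
                    "permutations": 999, "alpha": 0.05},
    "seed": 0,
    "out_prefix": "compare",
}


def _merge_config(config: dict[str, Any]) -> dict[str, Any]:
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in config.items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key].update(val)
        else:
            merged[key] = val
    return merged


@dataclass
class ComparisonSummary:
    aflp_loci_before: int
    aflp_loci_after: int
    snp_loci_before: int
    snp_loci_after: int
    n_matched_samples: int
    aflp_global_R: float
    aflp_anosim_p: float
    snp_global_R: float
    snp_anosim_p: float
    mantel_r: float
    mantel_p: float
    artifacts: dict[str, str] = field(default_factory=dict)
    manifest: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "locus_counts": {
                "aflp_before_qc": self.aflp_loci_before,
                "aflp_after_qc": self.aflp_loci_after,
                "snp_before_filter": self.snp_loci_before,
                "snp_after_filter": self.snp_loci_after,
            },
            "n_matched_samples": self.n_matched_samples,
            "anosim": {
                "aflp": {"global_R": self.aflp_global_R, "p": self.aflp_anosim_p,
                         "stars": significance_stars(self.aflp_anosim_p)},
                "snp": {"global_R": self.snp_global_R, "p": self.snp_anosim_p,
                        "stars": significance_stars(self.snp_anosim_p)},
            },
            "mantel": {"r": self.mantel_r, "p": self.mantel_p,
                       "stars": significance_stars(self.mantel_p)},
            "artifacts": self.artifacts,
            "manifest": self.manifest,
        }

    def text_table(self) -> str:
        lines = [
            "marker  n_loci(before)  n_samples  Global_R  Mantel_r",
            f"AFLP    {self.aflp_loci_after} ({self.aflp_loci_before})"
            f"  {self.n_matched_samples}"
            f"  {self.aflp_global_R:.3f}{significance_stars(self.aflp_anosim_p)}"
            f"  {self.mantel_r:.3f}{significance_stars(self.mantel_p)}",
            f"SNP     {self.snp_loci_after} ({self.snp_loci_before})"
            f"  {self.n_matched_samples}"
            f"  {self.snp_global_R:.3f}{significance_stars(self.snp_anosim_p)}"
            "  -",
            "stars: * p <= 0.05, ** p <= 0.01",
        ]
        return "\n".join(lines)


def _match_samples(
    aflp_meta: SampleMetadata,
    snp_meta: SampleMetadata,
    aflp_samples: list[str],
    snp_samples: list[str],
) -> list[tuple[str, str]]:
    """Join individuals across marker types on match_key (default sample id)."""
    a_key = {s: aflp_meta.match_key.get(s, s) for s in aflp_samples}
    s_key = {snp_meta.match_key.get(s, s): s for s in snp_samples}
    pairs = [(s, s_key[k]) for s, k in a_key.items() if k in s_key]
    if not pairs:
        raise StageError("match", "no samples joinable via match_key")
    return pairs


def run_compare(
    config: dict[str, Any],
    aflp: tuple[BinaryMarkerMatrix, SampleMetadata] | None = None,
    snp: tuple[GenotypeMatrix, SampleMetadata] | None = None,
    out_dir: str | Path | None = None,
) -> ComparisonSummary:
    """Run the full comparison.

    Inputs may be passed in-memory (``aflp``/``snp`` tuples) or read from
    the paths in the config.  When ``out_dir`` is given, artifacts
    (filtered matrix, QC log, distances, summary) are written under it.
    """
    cfg = _merge_config(config)
    t0 = time.time()
    seed = int(cfg["seed"])
    artifacts: dict[str, str] = {}
    outp = Path(out_dir) if out_dir is not None else None
    if outp is not None:
        outp.mkdir(parents=True, exist_ok=True)

    def stage(name: str):
        logger.info("stage=%s elapsed=%.1fs", name, time.time() - t0)

    # ---- load ----
    stage("load")
    try:
        if aflp is None:
            m = read_binary_marker_table(cfg["aflp"]["table"])
            a_meta = read_sample_metadata(cfg["aflp"]["meta"])
        else:
            m, a_meta = aflp
        if snp is None:
            g = read_genotype_table(cfg["snp"]["table"], format=cfg["snp"]["format"])
            s_meta = (
                read_sample_metadata(cfg["snp"]["meta"])
                if cfg["snp"]["meta"]
                else a_meta
            )
        else:
            g, s_meta = snp
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise StageError("load", str(exc)) from exc

    # ---- replicate-guided locus filter ----
    stage("qc_filter")
    pairs = [p for p in a_meta.replicate_pairs() if p[0] in m.sample_ids]
    aflp_before = m.n_loci
    if pairs:
        m_f, qc_log = aflp_qc.greedy_replicate_filter(
            m, pairs, iterate=bool(cfg["qc"]["iterate"])
        )
    else:
        logger.warning("no replicate pairs in metadata; skipping locus filter")
        m_f, qc_log = m, None
    if outp is not None and qc_log is not None:
        (outp / "qc_log.json").write_text(json.dumps(qc_log.to_dict(), indent=2))
        artifacts["qc_log"] = str(outp / "qc_log.json")

    # ---- optional ordination screen ----
    excluded: list[str] = []
    if cfg["qc"]["screen"]:
        stage("qc_screen")
        report = aflp_qc.nmds_outlier_screen(
            m_f.split_by_combo(),
            a_meta,
            coverage=cfg["qc"]["coverage"],
            indiv_threshold=cfg["qc"]["indiv_threshold"],
            combo_threshold=cfg["qc"]["combo_threshold"],
            seed=seed,
        )
        excluded = list(report.excluded_individuals)
        if report.excluded_combos:
            keep = [l for l in m_f.locus_ids
                    if m_f.primer_combo[l] not in report.excluded_combos]
            m_f = m_f.subset_loci(keep)
        if outp is not None:
            (outp / "screen_report.json").write_text(
                json.dumps(report.to_dict(), indent=2)
            )
            artifacts["screen_report"] = str(outp / "screen_report.json")

    # ---- drop replicates and excluded individuals ----
    m_f = m_f.drop_samples(set(a_meta.replicate_samples()) | set(excluded))
    if outp is not None:
        write_binary_marker_table(m_f, outp / "aflp_filtered.tsv")
        artifacts["aflp_filtered"] = str(outp / "aflp_filtered.tsv")

    # ---- SNP missingness filter ----
    stage("snp_filter")
    snp_before = g.n_loci
    g_f = filter_loci_by_missingness(g, float(cfg["snp"]["max_missing"]))

    # ---- match samples across marker types ----
    stage("match")
    pairs_ms = _match_samples(a_meta, s_meta, list(m_f.sample_ids),
                              list(g_f.sample_ids))
    a_order = [p[0] for p in pairs_ms]
    s_order = [p[1] for p in pairs_ms]
    m_m = m_f.subset_samples(a_order)
    g_m = g_f.subset_samples(s_order)

    # ---- distances ----
    stage("distances")
    try:
        d_aflp = dissimilarity.jaccard_matrix(m_m)
        d_snp_raw = dissimilarity.gower_matrix(g_m)
    except Exception as exc:  # noqa: BLE001
        raise StageError("distances", str(exc)) from exc
    # label the SNP matrix with the AFLP-side ids so everything aligns
    d_snp = DistanceMatrix(list(a_order), d_snp_raw.values)
    if outp is not None:
        write_distance_matrix(d_aflp, outp / "dist_aflp_jaccard.csv")
        write_distance_matrix(d_snp, outp / "dist_snp_gower.csv")
        artifacts["dist_aflp"] = str(outp / "dist_aflp_jaccard.csv")
        artifacts["dist_snp"] = str(outp / "dist_snp_gower.csv")

    # ---- statistics ----
    stage("stats")
    groups = {s: a_meta.region[s] for s in a_order}
    n_perm = int(cfg["stats"]["permutations"])
    a_res = inference_stats.anosim(d_aflp, groups, n_perm=n_perm, seed=seed)
    s_res = inference_stats.anosim(d_snp, groups, n_perm=n_perm, seed=seed + 1)
    mt = inference_stats.mantel(d_aflp, d_snp, n_perm=n_perm, seed=seed + 2)

    # ---- optional rarefaction ----
    if cfg["rarefaction"]["enabled"]:
        stage("rarefaction")
        rr = rarefaction.rarefaction_curves(
            g_m,
            {s: s_meta.region[s] for s in s_order},
            step=int(cfg["rarefaction"]["step"]),
            reps=int(cfg["rarefaction"]["reps"]),
            alpha=float(cfg["rarefaction"]["alpha"]),
            seed=seed,
            n_perm=int(cfg["rarefaction"]["permutations"]),
            extra_steps=[m_m.n_loci] if m_m.n_loci <= g_m.n_loci else [],
        )
        if m_m.n_loci <= g_m.n_loci:
            rr.aflp_overlay = rarefaction.aflp_overlay(
                d_aflp, groups, g_m, n_loci=m_m.n_loci,
                reps=int(cfg["rarefaction"]["reps"]), seed=seed,
                n_perm=int(cfg["rarefaction"]["permutations"]),
                match=dict(zip(a_order, s_order)),
            )
        if outp is not None:
            (outp / "rarefaction.json").write_text(json.dumps(rr.to_dict(), indent=2))
            artifacts["rarefaction"] = str(outp / "rarefaction.json")

    summary = ComparisonSummary(
        aflp_loci_before=aflp_before,
        aflp_loci_after=m_m.n_loci,
        snp_loci_before=snp_before,
        snp_loci_after=g_m.n_loci,
        n_matched_samples=len(a_order),
        aflp_global_R=a_res.global_R,
        aflp_anosim_p=a_res.p_value,
        snp_global_R=s_res.global_R,
        snp_anosim_p=s_res.p_value,
        mantel_r=mt.r,
        mantel_p=mt.p_value,
        artifacts=artifacts,
        manifest={"config": cfg, "seed": seed},
    )
    if outp is not None:
        (outp / "summary.json").write_text(json.dumps(summary.to_dict(), indent=2))
        (outp / "summary.txt").write_text(summary.text_table() + "\n")
    stage("done")
    return summary
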