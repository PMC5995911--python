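"""End-to-end pipeline: configuration, stage orchestration, run manifest.

The driver chains every stage in dependency order — tag loading, promoter
quantification, peak calling, overlap statistics, bivalent classification,
the Up/Other split, knockdown delta profiles and signature enrichment — and
writes plain-text artifacts (TSV/BED/JSON) plus a manifest.  Re-running
with identical inputs and seed reproduces byte-identical tables; only the
manifest timestamps differ.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .bivalent import build_signature, classify_promoters, enrichment_score, split_bivalent
from .intervals import promoter_windows
from .io import (BED_CONVENTION, read_chrom_sizes, read_de_table, read_signature,
                 read_tss_table)
from .peaks import call_peaks_poisson, consensus_overlap, read_peaks, venn_counts, write_peaks
from .signal import (NORMALIZATION_TARGET, TagCollection, anchor_matrix,
                     average_profile, delta_matrix, normalization_factor,
                     window_occupancy)
from .stats import wilcoxon_rank_sum

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

# the three marks whose knockdown response is profiled at Up-bivalent TSSs
PROFILE_MARKS = ("H2A.Z", "H3K27me3", "H3K4me3")


@dataclass
class PipelineConfig:
    """All inputs and parameters of one pipeline run.

    Parameter defaults are the analysis constants: 20,000,000-tag
    normalization target, 2 kb promoters, P <= 1e-8 peak threshold,
    >500 bp consensus-overlap rule, log2FC >= 1 & FDR <= 0.05 bivalent
    split, log2FC >= 5 signature construction.
    """

    tags: dict[tuple[str, str], str] = field(default_factory=dict)
    peaks: dict[tuple[str, str], str] = field(default_factory=dict)
    tss_path: str = ""
    chrom_sizes_path: str = ""
    de_path: str = ""
    signature_path: str | None = None
    differentiation_de_path: str | None = None
    outdir: str = "poised_out"
    seed: int = 0

    normalization_target: int = NORMALIZATION_TARGET
    promoter_width: int = 2000
    flank: int = 5000
    bin_size: int = 50
    min_overlap: int = 500
    p_threshold: float = 1e-8
    peak_window: int = 300
    peak_step: int = 100
    lfc: float = 1.0
    fdr: float = 0.05
    signature_lfc_min: float = 5.0
    n_perm: int = 1000
    enrichment_weight: float = 1.0
    overlap_pairwise: bool = False
    per_bp: bool = False  # report occupancy per bp instead of summed counts

    _SCALAR_KEYS = {
        "tss_path", "chrom_sizes_path", "de_path", "signature_path",
        "differentiation_de_path", "outdir", "seed", "normalization_target",
        "promoter_width", "flank", "bin_size", "min_overlap", "p_threshold",
        "peak_window", "peak_step", "lfc", "fdr", "signature_lfc_min",
        "n_perm", "enrichment_weight", "overlap_pairwise", "per_bp",
    }

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a flat key-value YAML config.

        Tag/peak inputs use dynamic keys ``tags_<mark>_<condition>`` and
        ``peaks_<mark>_<condition>``; every other key must name a known
        parameter — unknown keys are errors (typo guard).
        """
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("config must be a flat key-value mapping")
        kwargs: dict[str, Any] = {}
        tags: dict[tuple[str, str], str] = {}
        peaks: dict[tuple[str, str], str] = {}
        for key, value in raw.items():
            if key in cls._SCALAR_KEYS:
                kwargs[key] = value
            elif key.startswith("tags_") or key.startswith("peaks_"):
                prefix, rest = key.split("_", 1)
                mark, _, cond = rest.rpartition("_")
                if not mark or not cond:
                    raise ValueError(f"cannot parse mark/condition from key {key!r}")
                (tags if prefix == "tags" else peaks)[(mark, cond)] = str(value)
            else:
                raise ValueError(f"unknown config key {key!r}")
        return cls(tags=tags, peaks=peaks, **kwargs)

    def to_flat_dict(self) -> dict[str, Any]:
        d = {k: getattr(self, k) for k in sorted(self._SCALAR_KEYS)}
        for (mark, cond), p in sorted(self.tags.items()):
            d[f"tags_{mark}_{cond}"] = p
        for (mark, cond), p in sorted(self.peaks.items()):
            d[f"peaks_{mark}_{cond}"] = p
        return d

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_flat_dict(), fh, sort_keys=True)

    def validate(self) -> None:
        for name in ("tss_path", "chrom_sizes_path", "de_path"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"{name}: missing input {p!r}")
        for key, p in {**self.tags, **self.peaks}.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"input for {key} not found: {p}")
        if self.flank % self.bin_size:
            raise ValueError("flank must be divisible by bin_size")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, comment: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {BED_CONVENTION}\n# {comment}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute every stage and write the output bundle under ``config.outdir``.

    Returns a dict with the in-memory results (occupancy table, peak sets,
    overlap report, promoter states, bivalent split, profiles, enrichment,
    manifest).  Fails fast on missing inputs; on a stage failure the
    partial outputs already written are retained and the manifest records
    the failed stage.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict[str, Any] = {
        "tool": "poised",
        "version": __version__,
        "seed": config.seed,
        # hash covers analytic parameters and inputs, not the output location
        "config_hash": hashlib.sha256(
            json.dumps({k: v for k, v in config.to_flat_dict().items()
                        if k != "outdir"}, sort_keys=True).encode()
        ).hexdigest(),
        "inputs": {},
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime(t0)),
        "status": "running",
    }
    for name in ("tss_path", "chrom_sizes_path", "de_path"):
        manifest["inputs"][name] = _sha256(getattr(config, name))
    for (mark, cond), p in {**config.tags, **config.peaks}.items():
        manifest["inputs"][f"{mark}_{cond}"] = _sha256(p)

    results: dict[str, Any] = {"manifest": manifest}
    current_stage = "setup"
    try:
        # --- load inputs -------------------------------------------------
        current_stage = "load"
        genes = read_tss_table(config.tss_path)
        chrom_sizes = read_chrom_sizes(config.chrom_sizes_path)
        de = read_de_table(config.de_path)
        tags = {
            key: TagCollection.from_bed(path, sample_id=f"{key[0]}_{key[1]}",
                                        mark=key[0], condition=key[1]).dedup()
            for key, path in config.tags.items()
        }
        manifest["stages"]["load"] = {
            "n_genes": len(genes), "n_samples": len(tags), "n_de_rows": len(de),
        }
        logger.info("load: %d genes, %d tag samples, %d DE rows",
                    len(genes), len(tags), len(de))

        # --- promoter occupancy -----------------------------------------
        current_stage = "quantify"
        promoters = promoter_windows(genes, width=config.promoter_width,
                                     chrom_sizes=chrom_sizes)
        occ = pd.DataFrame(index=promoters["gene_id"])
        scales = {}
        for key, coll in sorted(tags.items()):
            scale = normalization_factor(coll, config.normalization_target)
            scales[key] = scale
            col = window_occupancy(coll, promoters, scale)
            if config.per_bp:
                col = col / (promoters["end"] - promoters["start"]).to_numpy()
            occ[f"{key[0]}_{key[1]}"] = col.to_numpy()
        _write_tsv(occ, outdir / "promoter_occupancy.tsv",
                   f"normalized promoter occupancy; target "
                   f"{config.normalization_target} tags; width "
                   f"{config.promoter_width} bp", index=True)
        results["occupancy"] = occ
        manifest["stages"]["quantify"] = {"n_promoters": len(promoters),
                                          "n_samples": len(tags)}

        # --- peak calling ------------------------------------------------
        current_stage = "callpeaks"
        peak_sets = {}
        for key in sorted(set(tags) | set(config.peaks)):
            if key in config.peaks:
                peak_sets[key] = read_peaks(config.peaks[key])
            else:
                peak_sets[key] = call_peaks_poisson(
                    tags[key], chrom_sizes, window=config.peak_window,
                    step=config.peak_step, p_threshold=config.p_threshold)
            write_peaks(peak_sets[key], outdir / f"peaks_{key[0].replace('.', '')}_{key[1]}.bed")
        results["peaks"] = peak_sets
        manifest["stages"]["callpeaks"] = {
            f"{m}_{c}": len(p) for (m, c), p in sorted(peak_sets.items())
        }

        # --- overlap statistics -------------------------------------------
        current_stage = "overlap"
        overlap_report: dict[str, Any] = {}
        ga, hz = ("GAS41", "control"), ("H2A.Z", "control")
        if ga in peak_sets and hz in peak_sets and peak_sets[ga]:
            res = consensus_overlap(peak_sets[ga], peak_sets[hz],
                                    min_overlap=config.min_overlap,
                                    pairwise=config.overlap_pairwise)
            overlap_report["GAS41_vs_H2A.Z"] = res.to_dict()
        venn_keys = [("GAS41", "control"), ("H3K27ac", "control"), ("H3K14ac", "control")]
        if all(k in peak_sets for k in venn_keys):
            overlap_report["venn_GAS41_H3K27ac_H3K14ac"] = venn_counts(
                {k[0]: peak_sets[k] for k in venn_keys},
                min_overlap=config.min_overlap)
        (outdir / "overlap_report.json").write_text(
            json.dumps(overlap_report, indent=2, sort_keys=True) + "\n")
        results["overlap"] = overlap_report
        manifest["stages"]["overlap"] = {"n_comparisons": len(overlap_report)}

        # --- bivalent classification and split ----------------------------
        current_stage = "bivalent"
        k4 = peak_sets.get(("H3K4me3", "control"), [])
        k27 = peak_sets.get(("H3K27me3", "control"), [])
        states = classify_promoters(promoters, k4, k27)
        _write_tsv(states, outdir / "promoter_states.tsv",
                   "promoter chromatin state from H3K4me3/H3K27me3 peak intersection")
        split = split_bivalent(states, de, lfc=config.lfc, fdr=config.fdr)
        split_counts = {"up": len(split.up), "down": len(split.down),
                        "no_change": len(split.no_change), "other": len(split.other)}
        split_df = pd.DataFrame(
            sorted([(g, "up") for g in split.up]
                   + [(g, "down") for g in split.down]
                   + [(g, "no_change") for g in split.no_change]),
            columns=["gene_id", "group"],
        )
        _write_tsv(split_df, outdir / "bivalent_split.tsv",
                   f"bivalent genes split at |log2FC| >= {config.lfc}, "
                   f"FDR <= {config.fdr}")
        results["states"], results["split"] = states, split
        manifest["stages"]["bivalent"] = {
            "n_active": int((states["state"] == "active").sum()),
            "n_bivalent": int((states["state"] == "bivalent").sum()),
            **split_counts,
        }
        logger.info("bivalent: %s", manifest["stages"]["bivalent"])

        # --- knockdown delta profiles at Up-bivalent TSSs ------------------
        current_stage = "profile"
        gene_by_id = {g.gene_id: g for g in genes}
        up_genes = [gene_by_id[g] for g in sorted(split.up) if g in gene_by_id]
        profile_stats: dict[str, Any] = {}
        for mark in PROFILE_MARKS:
            kc, cc = (mark, "kd"), (mark, "control")
            if not up_genes or kc not in tags or cc not in tags:
                continue
            m_kd = anchor_matrix(tags[kc], up_genes, flank=config.flank,
                                 bin_size=config.bin_size, scale=scales[kc])
            m_nt = anchor_matrix(tags[cc], up_genes, flank=config.flank,
                                 bin_size=config.bin_size, scale=scales[cc])
            delta = delta_matrix(m_kd, m_nt)
            prof_kd, prof_nt = average_profile(m_kd), average_profile(m_nt)
            prof = pd.DataFrame({
                "offset": prof_nt.offsets,
                "control": prof_nt.values,
                "kd": prof_kd.values,
                "delta": average_profile(delta).values,
            })
            safe = mark.replace(".", "")
            _write_tsv(prof, outdir / f"profile_{safe}_up_bivalent.tsv",
                       f"average TSS profile (±{config.flank} bp, "
                       f"{config.bin_size} bp bins) at Up-bivalent genes")
            up_ids = [g.gene_id for g in up_genes]
            occ_kd = occ.loc[up_ids, f"{mark}_kd"].to_numpy()
            occ_nt = occ.loc[up_ids, f"{mark}_control"].to_numpy()
            u, p = wilcoxon_rank_sum(occ_kd, occ_nt)
            profile_stats[mark] = {
                "mean_delta": float(delta.values.mean()),
                "wilcoxon_u": u, "wilcoxon_p": p, "n_genes": len(up_genes),
            }
        (outdir / "profile_stats.json").write_text(
            json.dumps(profile_stats, indent=2, sort_keys=True) + "\n")
        results["profile_stats"] = profile_stats
        manifest["stages"]["profile"] = {"marks": sorted(profile_stats),
                                         "n_up_genes": len(up_genes)}

        # --- signature enrichment -----------------------------------------
        current_stage = "enrich"
        signature = None
        if config.signature_path:
            members = read_signature(config.signature_path)
            if members:
                from .bivalent import GeneSignature
                signature = GeneSignature("signature", frozenset(members),
                                          rule=f"file:{config.signature_path}")
        elif config.differentiation_de_path:
            diff_de = read_de_table(config.differentiation_de_path)
            signature = build_signature(diff_de, lfc_min=config.signature_lfc_min)
        if signature is not None:
            ranked = de.set_index("gene_id")["log2fc"]
            enr = enrichment_score(ranked, signature,
                                   weight=config.enrichment_weight,
                                   n_perm=config.n_perm, seed=config.seed)
            (outdir / "enrichment.json").write_text(
                json.dumps({signature.name: enr.to_dict()}, indent=2,
                           sort_keys=True) + "\n")
            results["enrichment"] = enr
            manifest["stages"]["enrich"] = {"signature_size": len(signature.members),
                                            "es": enr.es, "p": enr.p}
        else:
            manifest["stages"]["enrich"] = {"skipped": "no signature input"}

        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = current_stage
        manifest["error"] = str(exc)
        _finalize_manifest(manifest, outdir, t0)
        raise
    _finalize_manifest(manifest, outdir, t0)
    return results


def _finalize_manifest(manifest: dict, outdir: Path, t0: float) -> None:
    t1 = time.time()
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime(t1))
    manifest["elapsed_s"] = round(t1 - t0, 3)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
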