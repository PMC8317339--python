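"""End-to-end orchestration: manifest, profiling run, group comparison.

The package is used from Python: a :class:`RunManifest` names the samples,
their inputs (BAM files or in-memory tables) and the filter thresholds, and
:func:`run_profile` / :func:`run_compare` execute the stages --
observation streaming, optional UMI consensus, the four filtering rules,
profile computation, and every group statistic -- writing TSV/JSON outputs
when an output directory is given.  A per-rule attrition log accounts for
every base: ``bases_in = bases_retained + sum(removed by each rule)``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import group_stats, profiling, umi_des
from .datamodel import ErrorProfile, FragmentBinProfile, SampleMeta, validate_pairing
from .observations import load_panel, stream_observations
from .profiling import FilterConfig
from .synthetic import SimulatedDataset

logger = logging.getLogger("bgerr")


@dataclass
class RunManifest:
    """Inputs and configuration of one profiling run."""

    samples: list[SampleMeta]
    filter: FilterConfig = field(default_factory=FilterConfig)
    mode: str = "counts"  # "counts" | "reads"
    counts: dict[str, pd.DataFrame] | None = None
    observations: dict[str, pd.DataFrame] | None = None
    bam_paths: dict[str, Path] | None = None
    panel_path: Path | None = None
    reference_path: Path | None = None
    use_des: bool = True
    outdir: Path | None = None
    seed: int = 0

    def validate(self) -> "RunManifest":
        """Fail fast, before any compute: pairing and input completeness."""
        pairs = validate_pairing(self.samples)
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_ids in manifest")
        if self.mode == "counts":
            if self.counts is None:
                raise ValueError("counts-mode manifest needs count tables")
            missing = [s for s in ids if s not in self.counts]
        elif self.mode == "reads":
            if self.bam_paths is not None:
                missing = [s for s in ids if s not in self.bam_paths]
                for sid, p in (self.bam_paths or {}).items():
                    if not Path(p).exists():
                        raise FileNotFoundError(f"sample {sid}: {p} does not exist")
                for name, p in (("panel", self.panel_path),
                                ("reference", self.reference_path)):
                    if p is None or not Path(p).exists():
                        raise FileNotFoundError(f"{name} path missing for reads mode")
            elif self.observations is not None:
                missing = [s for s in ids if s not in self.observations]
            else:
                raise ValueError("reads-mode manifest needs BAM paths or observations")
        else:
            raise ValueError(f"unknown mode {self.mode!r}")
        if missing:
            raise ValueError(f"manifest lacks inputs for samples {missing}")
        self._pairs = pairs
        return self

    @classmethod
    def from_simulated(
        cls,
        ds: SimulatedDataset,
        filt: FilterConfig | None = None,
        use_des: bool = True,
        outdir: str | Path | None = None,
    ) -> "RunManifest":
        """Manifest pointing at a :func:`simulate_counts` / ``simulate_reads`` output."""
        mode = "counts" if ds.counts else "reads"
        return cls(
            samples=list(ds.samples),
            filter=filt or FilterConfig(),
            mode=mode,
            counts=dict(ds.counts) if ds.counts else None,
            observations=dict(ds.observations) if ds.observations else None,
            bam_paths=dict(ds.bam_paths) if ds.bam_paths else None,
            panel_path=ds.panel_path,
            reference_path=ds.reference_path,
            use_des=use_des and mode == "reads",
            outdir=Path(outdir) if outdir else None,
            seed=ds.ledger.seed,
        ).validate()


@dataclass
class ProfileRun:
    """Everything :func:`run_profile` computes for one manifest."""

    manifest: RunManifest
    site_counts: dict[str, pd.DataFrame]
    masks: dict[str, frozenset]            # per sample (shared within a pair)
    profiles: dict[str, ErrorProfile]
    raw_profiles: dict[str, ErrorProfile] = field(default_factory=dict)
    bin_profiles: dict[str, FragmentBinProfile] = field(default_factory=dict)
    error_free: dict[str, float] = field(default_factory=dict)
    attrition: dict[str, dict] = field(default_factory=dict)

    def by_group(self) -> dict[str, list[ErrorProfile]]:
        out: dict[str, list[ErrorProfile]] = {}
        for s in self.manifest.samples:
            out.setdefault(s.sample_type, []).append(self.profiles[s.sample_id])
        return out

    def pair_depths(self, sample_id: str) -> list[pd.DataFrame]:
        for pair in self.manifest._pairs.values():
            sids = [s.sample_id for s in pair]
            if sample_id in sids:
                return [self.site_counts[s] for s in sids if s != sample_id]
        return []


def _observation_frames(manifest: RunManifest) -> dict[str, pd.DataFrame]:
    if manifest.observations is not None:
        return manifest.observations
    panel = load_panel(manifest.panel_path)
    frames = {}
    for sid, bam in manifest.bam_paths.items():
        logger.info("streaming observations for %s from %s", sid, bam)
        frames[sid] = profiling.observations_to_frame(
            stream_observations(bam, panel, manifest.reference_path)
        )
    return frames


def run_profile(manifest: RunManifest) -> ProfileRun:
    """Observations -> (optional) UMI consensus -> filters -> profiles.

    In reads mode both the raw and the consensus (DES) profile are computed
    so their comparison -- the error-rate reduction digital error
    suppression achieves -- is always available.  Outputs (profile TSVs,
    JSON sidecars, attrition log) are written under ``manifest.outdir``
    when set.  Deterministic: same inputs, same outputs.
    """
    manifest.validate()
    filt = manifest.filter
    attrition: dict[str, dict] = {}
    raw_counts: dict[str, pd.DataFrame] = {}
    site_counts: dict[str, pd.DataFrame] = {}
    obs_frames: dict[str, pd.DataFrame] = {}
    bin_source: dict[str, pd.DataFrame] = {}

    if manifest.mode == "counts":
        site_counts = {sid: df for sid, df in manifest.counts.items()}
    else:
        obs_frames = _observation_frames(manifest)
        for sid, frame in obs_frames.items():
            if manifest.use_des and "umi" not in frame.columns:
                raise ValueError(
                    "use_des requires UMI-family columns in the observations "
                    "(lean frames carry none)")
            att: dict = {}
            raw_counts[sid] = profiling.build_site_counts(frame, filt, attrition=att)
            if manifest.use_des:
                consensus = umi_des.suppress_frame(frame)
                att["reads_collapsed_by_des"] = len(frame) - len(consensus)
                site_counts[sid] = profiling.build_site_counts(consensus, filt)
                bin_source[sid] = consensus
            else:
                site_counts[sid] = raw_counts[sid]
                bin_source[sid] = frame
            attrition[sid] = att

    # rule 4: pairwise germline/blacklist masking on filtered depths
    masks: dict[str, frozenset] = {}
    for pair_id, (cf, gd) in manifest._pairs.items():
        mask = profiling.apply_pairwise_variant_exclusion(
            site_counts[cf.sample_id], site_counts[gd.sample_id], filt)
        masks[cf.sample_id] = mask
        masks[gd.sample_id] = mask
        logger.info("pair %s: %d masked alleles", pair_id, len(mask))

    run = ProfileRun(manifest=manifest, site_counts=site_counts, masks=masks,
                     profiles={}, attrition=attrition)
    for s in manifest.samples:
        sid = s.sample_id
        pair_depths = [site_counts[o.sample_id]
                       for o in _pair_members(manifest, sid)]
        run.profiles[sid] = profiling.compute_error_profile(
            site_counts[sid], filt, sid, masks[sid], pair_depths)
        run.error_free[sid] = profiling.error_free_fraction(
            site_counts[sid], filt, masks[sid], pair_depths)
        if manifest.mode == "reads":
            if manifest.use_des:
                raw_pair = [raw_counts[o.sample_id]
                            for o in _pair_members(manifest, sid)]
                run.raw_profiles[sid] = profiling.compute_error_profile(
                    raw_counts[sid], filt, sid, masks[sid], raw_pair)
            sc = site_counts[sid]
            deep = sc[sc["depth"] >= filt.min_depth]
            eligible = list(zip(deep["chrom"], deep["pos"].astype(int)))
            run.bin_profiles[sid] = profiling.fragment_bin_profile(
                bin_source[sid], filt, sid, masks[sid],
                eligible_positions=eligible)
    if manifest.outdir:
        _write_profile_outputs(run)
    return run


def _pair_members(manifest: RunManifest, sample_id: str) -> list[SampleMeta]:
    for pair in manifest._pairs.values():
        sids = [s.sample_id for s in pair]
        if sample_id in sids:
            return [s for s in pair if s.sample_id != sample_id]
    return []


def _write_profile_outputs(run: ProfileRun) -> None:
    outdir = Path(run.manifest.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "min_base_quality": run.manifest.filter.min_base_quality,
        "min_depth": run.manifest.filter.min_depth,
        "germline_af_threshold": run.manifest.filter.germline_af_threshold,
        "use_des": run.manifest.use_des,
        "seed": run.manifest.seed,
    }
    for sid, profile in run.profiles.items():
        profile.write(outdir / f"{sid}.profile.tsv", metadata=meta)
    for sid, bp in run.bin_profiles.items():
        bp.write(outdir / f"{sid}.bins.tsv", metadata=meta)
    (outdir / "attrition.json").write_text(json.dumps(run.attrition, indent=2))
    (outdir / "error_free.json").write_text(json.dumps(run.error_free, indent=2))


@dataclass
class CompareResult:
    class_comparison: pd.DataFrame
    class_comparison_collapsed: pd.DataFrame
    position_table: pd.DataFrame
    position_hits: group_stats.PositionHitList
    reprofile_deltas: pd.DataFrame
    bin_contrasts: dict[str, pd.DataFrame] | None = None
    des_reduction: dict[str, dict] | None = None


def run_compare(
    run: ProfileRun,
    class_alpha: float = 0.01,
    position_alpha: float = 0.05,
    position_correction: str = "bonferroni",
) -> CompareResult:
    """All group statistics for a profiled cfDNA-vs-gDNA dataset.

    Class-wise Welch tests (directional and collapsed, Bonferroni within
    the class family), per-position tests with the hit list, re-profiling
    after excluding the hit positions, breakpoint-bin contrasts (reads
    mode), and per-sample DES error-rate reductions (when consensus ran).
    """
    manifest = run.manifest
    by_group = run.by_group()
    groups = {s.sample_id: s.sample_type for s in manifest.samples}
    cls_cmp = group_stats.compare_class_rates(by_group, alpha=class_alpha)
    cls_cmp_collapsed = group_stats.compare_class_rates(
        by_group, alpha=class_alpha, collapsed=True)

    table = profiling.position_error_table(
        run.site_counts, manifest.filter,
        mask=frozenset().union(*run.masks.values()) if run.masks else frozenset())
    hits = group_stats.compare_positions(
        table, groups, alpha=position_alpha, correction=position_correction)
    _, _, deltas = group_stats.exclude_and_reprofile(
        hits.hit_positions(), run.site_counts, manifest.filter,
        masks_by_sample=run.masks,
        pair_depths_by_sample={s.sample_id: run.pair_depths(s.sample_id)
                               for s in manifest.samples})

    bin_contrasts = None
    if run.bin_profiles:
        bins_by_group: dict[str, list[FragmentBinProfile]] = {}
        for s in manifest.samples:
            bins_by_group.setdefault(s.sample_type, []).append(
                run.bin_profiles[s.sample_id])
        bin_contrasts = group_stats.compare_bins(bins_by_group, alpha=class_alpha)

    des_reduction = None
    if run.raw_profiles:
        des_reduction = {
            sid: umi_des.des_effect(run.raw_profiles[sid], run.profiles[sid])
            for sid in run.raw_profiles
        }
    result = CompareResult(
        class_comparison=cls_cmp,
        class_comparison_collapsed=cls_cmp_collapsed,
        position_table=table,
        position_hits=hits,
        reprofile_deltas=deltas,
        bin_contrasts=bin_contrasts,
        des_reduction=des_reduction,
    )
    if manifest.outdir:
        outdir = Path(manifest.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cls_cmp.to_csv(outdir / "class_comparison.tsv", sep="\t", index=False)
        cls_cmp_collapsed.to_csv(
            outdir / "class_comparison_collapsed.tsv", sep="\t", index=False)
        hits.hits.to_csv(outdir / "position_hits.tsv", sep="\t", index=False)
        table.to_csv(outdir / "position_table.tsv", sep="\t", index=False)
        hits.to_bed(outdir / "position_hits.bed")
        deltas.to_csv(outdir / "reprofile_deltas.tsv", sep="\t", index=False)
        summary = {
            "n_hits": hits.n_hits,
            "n_tested": hits.n_tested,
            "fraction_hits": hits.fraction,
            "significant_classes": cls_cmp.loc[cls_cmp["significant"], "class"].tolist(),
        }
        (outdir / "comparison_summary.json").write_text(json.dumps(summary, indent=2))
    return result


__all__ = ["RunManifest", "ProfileRun", "CompareResult", "run_profile", "run_compare"]
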