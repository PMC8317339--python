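"""Background-error filtering and rate estimation.

Four rules turn a raw pileup into background-error counts:

1. the reference allele is never an error;
2. bases below a Phred quality threshold (default Q30) are removed;
3. genomic positions below a minimum depth (default 500x, evaluated jointly
   across a sample pair or across all samples for group tables) are removed;
4. any alternate allele above a germline allele-fraction threshold (default
   1%) in *either* member of a cfDNA/gDNA pair is excluded from error
   counting in both members, as are user-blacklisted variants.

What remains is counted into 12 directional substitution classes.  Rates are
errors per eligible base, with reference-base opportunities as the default
denominator (``C>T`` errors divided by the number of sequenced bases whose
reference is C); a total-base denominator is available on
:class:`~bgerr.datamodel.ErrorProfile`.

This module also derives the per-position error table, the fraction of
error-free positions, the 5-bp fragment-breakpoint bin profile, and 96-channel
trinucleotide spectra with a non-negative signature refit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .datamodel import (
    ALL_CLASSES,
    BASES,
    COMPLEMENT,
    BaseObservation,
    ErrorProfile,
    FragmentBinProfile,
    SubstitutionClass,
    validate_site_counts,
)

MaskSet = frozenset  # of (chrom, pos, alt_base)

OBS_COLUMNS = ["chrom", "pos", "ref", "obs", "qual", "dist"]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the four background-error filtering rules."""

    min_base_quality: int = 30
    min_depth: int = 500
    germline_af_threshold: float = 0.01
    variant_blacklist: frozenset = frozenset()  # of (chrom, pos, alt)

    def __post_init__(self) -> None:
        if self.min_base_quality < 0 or self.min_depth < 1:
            raise ValueError("thresholds must be positive")
        if not (0.0 < self.germline_af_threshold < 1.0):
            raise ValueError("germline_af_threshold must be in (0, 1)")


def load_variant_blacklist(path) -> frozenset:
    """Read a variant blacklist as a set of (chrom, 0-based pos, alt).

    Accepts an uncompressed/bgzipped VCF (``.vcf``/``.vcf.gz``; one entry
    per ALT allele, coordinates converted from VCF's 1-based convention) or
    a 3-column TSV of ``chrom  pos(0-based)  alt``.
    """
    path = str(path)
    entries: set[tuple[str, int, str]] = set()
    if path.endswith((".vcf", ".vcf.gz")):
        import pysam

        with pysam.VariantFile(path) as vcf:
            for rec in vcf:
                for alt in rec.alts or ():
                    if alt in BASES:
                        entries.add((rec.chrom, rec.start, alt))
    else:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"{path}:{lineno}: expected 3 columns")
                entries.add((fields[0], int(fields[1]), fields[2]))
    return frozenset(entries)


def dedup_mate_overlap(frame: pd.DataFrame) -> pd.DataFrame:
    """Keep one observation per read pair and position (single-count mode).

    Where the two mates of a pair overlap, the default pileup counts the
    position twice; this keeps only the higher-quality mate's observation.
    Requires the ``pair_id`` column carried by full observation frames.
    """
    if "pair_id" not in frame.columns:
        raise ValueError("mate-overlap dedup needs the pair_id column")
    order = frame.sort_values("qual", ascending=False, kind="stable")
    out = order.drop_duplicates(subset=["pair_id", "chrom", "pos"])
    return out.sort_index().reset_index(drop=True)


def observations_to_frame(observations: Iterable[BaseObservation]) -> pd.DataFrame:
    """Materialize an observation stream as a DataFrame.

    Keeps the full observation tuple; downstream tallies use the
    ``chrom/pos/ref/obs/qual/dist`` columns, UMI consensus additionally the
    family-key columns.
    """
    obs_list = list(observations)
    if not obs_list:
        empty = pd.DataFrame(columns=BaseObservation._fields).rename(
            columns={"ref_base": "ref", "obs_base": "obs",
                     "base_quality": "qual", "dist_from_breakpoint": "dist"})
        empty["pair_id"] = pd.Series(dtype=object)
        return empty
    df = pd.DataFrame(obs_list, columns=BaseObservation._fields)
    df = df.rename(columns={"ref_base": "ref", "obs_base": "obs",
                            "base_quality": "qual", "dist_from_breakpoint": "dist"})
    df["pair_id"] = df["read_id"].str.rsplit("/", n=1).str[0]
    return df


def _as_frame(observations) -> pd.DataFrame:
    if isinstance(observations, pd.DataFrame):
        return observations
    return observations_to_frame(observations)


def _base_codes(s: pd.Series) -> np.ndarray:
    """A/C/G/T -> 0..3; assumes values are restricted to the four bases."""
    if isinstance(s.dtype, pd.CategoricalDtype) and list(s.cat.categories) == list(BASES):
        return s.cat.codes.to_numpy()
    return np.searchsorted(np.array(BASES), s.to_numpy())


def build_site_counts(
    observations,
    filt: FilterConfig,
    attrition: dict | None = None,
) -> pd.DataFrame:
    """Tally quality-filtered observations into a per-position allele table.

    Accepts an iterable of :class:`BaseObservation` (or consensus
    observations) or an equivalent DataFrame.  Bases below
    ``filt.min_base_quality`` are dropped; the returned table has one row
    per covered position with columns ``chrom, pos, ref, A, C, G, T, depth``.
    If ``attrition`` is a dict, per-rule removal counts are accumulated into
    it (keys ``bases_in``, ``removed_low_quality``, ``bases_retained``).
    """
    df = _as_frame(observations)
    n_in = len(df)
    if n_in:
        df = df[df["qual"] >= filt.min_base_quality]
    if attrition is not None:
        attrition["bases_in"] = attrition.get("bases_in", 0) + n_in
        attrition["removed_low_quality"] = (
            attrition.get("removed_low_quality", 0) + n_in - len(df)
        )
        attrition["bases_retained"] = attrition.get("bases_retained", 0) + len(df)
    if not len(df):
        from .datamodel import empty_site_counts

        return empty_site_counts()
    # bincount tally over (site, ref, obs) codes: linear in observations
    chrom_codes, chrom_cats = pd.factorize(df["chrom"], sort=True)
    pos = df["pos"].to_numpy(dtype=np.int64)
    ref_codes = _base_codes(df["ref"])
    obs_codes = _base_codes(df["obs"])
    site_key = chrom_codes.astype(np.int64) * (pos.max() + 1) + pos
    sites, site_codes = np.unique(site_key, return_inverse=True)
    combo = site_codes * 16 + ref_codes.astype(np.int64) * 4 + obs_codes
    tally = np.bincount(combo, minlength=len(sites) * 16).reshape(len(sites), 4, 4)
    per_ref = tally.sum(axis=2)  # observations per (site, ref)
    ref_of_site = per_ref.argmax(axis=1)
    counts = tally[np.arange(len(sites)), ref_of_site, :]
    out = pd.DataFrame(counts, columns=list(BASES))
    out.insert(0, "ref", np.array(list(BASES))[ref_of_site])
    out.insert(0, "pos", (sites % (pos.max() + 1)).astype(np.int64))
    out.insert(0, "chrom", np.asarray(chrom_cats)[sites // (pos.max() + 1)])
    out["depth"] = out[list(BASES)].sum(axis=1)
    out = out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    return validate_site_counts(out)


def apply_pairwise_variant_exclusion(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    filt: FilterConfig,
) -> MaskSet:
    """Alleles to exclude from error counting in *both* members of a pair.

    An (chrom, pos, alt) allele is masked when its allele fraction exceeds
    ``filt.germline_af_threshold`` in either the cfDNA or the gDNA member
    (putative germline variation), or when it is blacklisted (e.g. known
    somatic variants of a tumor cohort).  Other alternate alleles at the
    same site remain countable.
    """
    masked: set[tuple[str, int, str]] = set(filt.variant_blacklist)
    for df in (counts_a, counts_b):
        if not len(df):
            continue
        depth = df["depth"].to_numpy()
        ok = depth > 0
        for b in BASES:
            af = np.zeros(len(df))
            af[ok] = df[b].to_numpy()[ok] / depth[ok]
            hot = (af > filt.germline_af_threshold) & (df["ref"].to_numpy() != b)
            for chrom, pos in zip(df["chrom"].to_numpy()[hot], df["pos"].to_numpy()[hot]):
                masked.add((chrom, int(pos), b))
    return frozenset(masked)


def _eligibility(
    counts: pd.DataFrame,
    filt: FilterConfig,
    pair_depths: Sequence[pd.DataFrame] | None = None,
    exclude_positions: Iterable[tuple[str, int]] | None = None,
) -> np.ndarray:
    """Boolean row mask: depth >= min_depth here and in every companion table."""
    elig = counts["depth"].to_numpy() >= filt.min_depth
    if pair_depths:
        key = pd.MultiIndex.from_frame(counts[["chrom", "pos"]])
        for other in pair_depths:
            other_depth = other.set_index(["chrom", "pos"])["depth"]
            aligned = other_depth.reindex(key).fillna(0).to_numpy()
            elig &= aligned >= filt.min_depth
    if exclude_positions:
        excl = set(exclude_positions)
        if excl:
            keys = list(zip(counts["chrom"], counts["pos"].astype(int)))
            elig &= np.array([k not in excl for k in keys])
    return elig


def _masked_depth_per_row(sub: pd.DataFrame, mask: MaskSet) -> np.ndarray:
    """Per-row total depth of masked non-reference alleles."""
    out = np.zeros(len(sub), dtype=np.int64)
    if not mask:
        return out
    loc = {(c, int(p)): i for i, (c, p) in enumerate(zip(sub["chrom"], sub["pos"]))}
    refs = sub["ref"].to_numpy()
    for chrom, pos, alt in mask:
        i = loc.get((chrom, int(pos)))
        if i is not None and refs[i] != alt:
            out[i] += int(sub.iloc[i][alt])
    return out


def compute_error_profile(
    counts: pd.DataFrame,
    filt: FilterConfig,
    sample_id: str,
    mask: MaskSet = frozenset(),
    pair_depths: Sequence[pd.DataFrame] | None = None,
    exclude_positions: Iterable[tuple[str, int]] | None = None,
) -> ErrorProfile:
    """Count unmasked non-reference alleles at depth-eligible positions.

    ``pair_depths`` are companion count tables (the pair member, or all
    samples of a group analysis); a position must reach ``min_depth`` in the
    sample *and* every companion to be eligible.  ``exclude_positions``
    supports the exclude-then-reprofile workflow.  Masked allele depths are
    removed from the numerator only; the denominator is the total retained
    depth at eligible positions.
    """
    elig = _eligibility(counts, filt, pair_depths, exclude_positions)
    allele = counts[list(BASES)].to_numpy()[elig]
    refc = _base_codes(counts["ref"])[elig]
    tally = np.zeros((4, 4), dtype=np.int64)
    for r in range(4):
        rows = refc == r
        if rows.any():
            tally[r] = allele[rows].sum(axis=0)
    eligible_bases = {b: int(tally[i].sum()) for i, b in enumerate(BASES)}
    error_counts: dict[SubstitutionClass, int] = {
        c: int(tally[BASES.index(c.ref_base), BASES.index(c.alt_base)])
        for c in ALL_CLASSES
    }
    # subtract masked alleles from their class numerators
    if mask:
        chroms = counts["chrom"].to_numpy()[elig]
        positions = counts["pos"].to_numpy()[elig]
        loc = {(ch, int(p)): i for i, (ch, p) in enumerate(zip(chroms, positions))}
        for chrom, pos, alt in mask:
            i = loc.get((chrom, int(pos)))
            if i is None:
                continue
            ref = BASES[refc[i]]
            if ref != alt:
                error_counts[SubstitutionClass(ref, alt)] -= int(
                    allele[i, BASES.index(alt)])
    return ErrorProfile(
        sample_id=sample_id,
        error_counts=error_counts,
        eligible_bases=eligible_bases,
        n_eligible_positions=int(elig.sum()),
    )


def error_free_fraction(
    counts: pd.DataFrame,
    filt: FilterConfig,
    mask: MaskSet = frozenset(),
    pair_depths: Sequence[pd.DataFrame] | None = None,
    exclude_positions: Iterable[tuple[str, int]] | None = None,
) -> float:
    """Percentage of eligible positions carrying zero unmasked errors."""
    elig = _eligibility(counts, filt, pair_depths, exclude_positions)
    sub = counts[elig].reset_index(drop=True)
    if not len(sub):
        return float("nan")
    allele = sub[list(BASES)].to_numpy()
    ref_idx = np.searchsorted(np.array(BASES), sub["ref"].to_numpy())
    ref_depth = allele[np.arange(len(sub)), ref_idx]
    err = sub["depth"].to_numpy() - ref_depth - _masked_depth_per_row(sub, mask)
    return 100.0 * float((err == 0).mean())


def position_error_table(
    counts_by_sample: Mapping[str, pd.DataFrame],
    filt: FilterConfig,
    mask: MaskSet = frozenset(),
) -> pd.DataFrame:
    """Per-position, per-class, per-sample error rates on the common mask.

    Positions must reach ``min_depth`` in **all** samples to be eligible;
    ineligible positions are absent for every sample.  Emits one row per
    (position, class, sample) for the three non-reference classes at each
    site, plus a pooled ``total`` class (all unmasked alternate alleles),
    since per-position rates can be read either way.
    """
    samples = list(counts_by_sample)
    if not samples:
        return pd.DataFrame(columns=["chrom", "pos", "ref", "class", "sample_id", "rate"])
    base = counts_by_sample[samples[0]]
    elig = _eligibility(
        base, filt, [counts_by_sample[s] for s in samples[1:]]
    )
    key = base.loc[elig, ["chrom", "pos", "ref"]].reset_index(drop=True)
    frames = []
    for sid in samples:
        df = counts_by_sample[sid].set_index(["chrom", "pos"])
        sub = df.reindex(pd.MultiIndex.from_frame(key[["chrom", "pos"]]))
        depth = sub["depth"].to_numpy(dtype=float)
        refs = key["ref"].to_numpy()
        masked_alt = np.zeros((len(key), 4))
        if mask:
            loc = {(c, int(p)): i for i, (c, p) in enumerate(zip(key["chrom"], key["pos"]))}
            for chrom, pos, alt in mask:
                i = loc.get((chrom, int(pos)))
                if i is not None:
                    masked_alt[i, BASES.index(alt)] = 1
        total_err = np.zeros(len(key))
        for bi, b in enumerate(BASES):
            alt_rows = refs != b
            is_masked = masked_alt[:, bi] == 1
            use = alt_rows & ~is_masked
            cnt = sub[b].to_numpy(dtype=float)
            rate = np.where(depth > 0, cnt / depth, np.nan)
            total_err += np.where(use, cnt, 0.0)
            sel = use.nonzero()[0]
            frames.append(pd.DataFrame({
                "chrom": key["chrom"].to_numpy()[sel],
                "pos": key["pos"].to_numpy()[sel],
                "ref": refs[sel],
                "class": [f"{r}>{b}" for r in refs[sel]],
                "sample_id": sid,
                "rate": rate[sel],
            }))
        frames.append(pd.DataFrame({
            "chrom": key["chrom"], "pos": key["pos"], "ref": refs,
            "class": "total", "sample_id": sid,
            "rate": np.where(depth > 0, total_err / depth, np.nan),
        }))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "pos", "class", "sample_id"]).reset_index(drop=True)


def fragment_bin_profile(
    observations,
    filt: FilterConfig,
    sample_id: str,
    mask: MaskSet = frozenset(),
    eligible_positions: Iterable[tuple[str, int]] | None = None,
) -> FragmentBinProfile:
    """Tally errors and opportunities into ten 5-bp breakpoint bins.

    Observations (raw or consensus) at read positions 1..50 from the 5' end
    are assigned to bins ``ceil(dist/5)``; farther bases are not binned.
    Quality filtering and allele masking follow the standard rules; if
    ``eligible_positions`` is given, only those genomic positions
    contribute (depth eligibility is decided by the caller, who has the
    site-count tables).
    """
    df = _as_frame(observations)
    if len(df):
        df = df[(df["qual"] >= filt.min_base_quality) & (df["dist"] <= 50) & (df["dist"] >= 1)]
    if eligible_positions is not None and len(df):
        by_chrom: dict[str, list[int]] = {}
        for chrom, pos in eligible_positions:
            by_chrom.setdefault(chrom, []).append(pos)
        keep = np.zeros(len(df), dtype=bool)
        pos_arr = df["pos"].to_numpy()
        chrom_arr = df["chrom"].to_numpy()
        for chrom, positions in by_chrom.items():
            rows = chrom_arr == chrom
            keep[rows] = np.isin(pos_arr[rows], np.asarray(positions))
        df = df[keep]
    bins = pd.RangeIndex(1, 11, name="bin")
    class_cols = [str(c) for c in ALL_CLASSES]
    counts = pd.DataFrame(0, index=bins, columns=class_cols)
    elig_bases = pd.DataFrame(0, index=bins, columns=list(BASES))
    if len(df):
        bin_codes = (df["dist"].to_numpy(dtype=np.int64) + 4) // 5  # 1..10
        ref_codes = _base_codes(df["ref"]).astype(np.int64)
        obs_codes = _base_codes(df["obs"]).astype(np.int64)
        masked = np.zeros(len(df), dtype=bool)
        if mask:
            mask_df = pd.DataFrame(sorted(mask), columns=["chrom", "pos", "__alt"])
            mask_df["__masked"] = True
            joined = df[["chrom", "pos"]].assign(
                __alt=np.array(list(BASES))[obs_codes]).merge(
                mask_df, on=["chrom", "pos", "__alt"], how="left")
            masked = joined["__masked"].notna().to_numpy()
        combo = (bin_codes - 1) * 16 + ref_codes * 4 + obs_codes
        opp = np.bincount(combo, minlength=160).reshape(10, 4, 4)
        err = np.bincount(combo[~masked & (ref_codes != obs_codes)],
                          minlength=160).reshape(10, 4, 4)
        elig_bases.loc[:, list(BASES)] = opp.sum(axis=2)
        for c in ALL_CLASSES:
            counts[str(c)] = err[:, BASES.index(c.ref_base), BASES.index(c.alt_base)]
    return FragmentBinProfile(sample_id=sample_id, bin_counts=counts,
                              bin_eligible_bases=elig_bases)


# ---------------------------------------------------------------------------
# Trinucleotide spectra and signature refitting
# ---------------------------------------------------------------------------

def spectrum_channels() -> list[str]:
    """The 96 channel labels, pyrimidine-centric, e.g. ``A[C>T]G``."""
    channels = []
    for ref in ("C", "T"):
        for alt in BASES:
            if alt == ref:
                continue
            for five in BASES:
                for three in BASES:
                    channels.append(f"{five}[{ref}>{alt}]{three}")
    return channels


@dataclass
class TrinucSpectrum:
    """96-channel substitution spectrum over trinucleotide contexts."""

    counts: pd.Series  # indexed by spectrum_channels()
    n_dropped_edge: int = 0

    @property
    def fractions(self) -> pd.Series:
        total = self.counts.sum()
        return self.counts / total if total > 0 else self.counts.astype(float)

    def write(self, tsv_path) -> None:
        self.fractions.rename("fraction").to_frame().assign(
            count=self.counts).rename_axis("channel").to_csv(tsv_path, sep="\t")


def _channel(five: str, ref: str, alt: str, three: str) -> str:
    if ref not in ("C", "T"):  # purine reference: use the reverse-complement strand
        five, ref, alt, three = (
            COMPLEMENT[three], COMPLEMENT[ref], COMPLEMENT[alt], COMPLEMENT[five]
        )
    return f"{five}[{ref}>{alt}]{three}"


def trinuc_spectrum(
    errors: Iterable[tuple[str, int, str, str]],
    reference: Mapping[str, str],
) -> TrinucSpectrum:
    """Build the 96-channel spectrum of error events.

    ``errors`` yields (chrom, pos, ref, alt) events (one per errored base);
    ``reference`` maps chromosome name to its sequence (a pyfaidx Fasta
    works).  Events at contig edges or with ambiguous context are dropped
    and counted in ``n_dropped_edge``.
    """
    counts = pd.Series(0, index=spectrum_channels(), dtype=np.int64)
    dropped = 0
    for chrom, pos, ref, alt in errors:
        seq = reference[chrom]
        if pos < 1 or pos + 1 >= len(seq):
            dropped += 1
            continue
        five, mid, three = str(seq[pos - 1]).upper(), str(seq[pos]).upper(), str(seq[pos + 1]).upper()
        if mid != ref or any(b not in BASES for b in (five, ref, alt, three)):
            dropped += 1
            continue
        counts[_channel(five, ref, alt, three)] += 1
    return TrinucSpectrum(counts=counts, n_dropped_edge=dropped)


def refit_signatures(
    spectrum: TrinucSpectrum, signatures: pd.DataFrame
) -> pd.Series:
    """Non-negative least-squares refit of a spectrum against signatures.

    ``signatures`` is 96 x k with columns summing to 1 (COSMIC-style).
    Returns per-signature weights normalized to fractions of the total
    (summing to 1 when any weight is positive).
    """
    if list(signatures.index) != spectrum_channels():
        signatures = signatures.reindex(spectrum_channels())
        if signatures.isna().any().any():
            raise ValueError("signature matrix must cover all 96 trinucleotide channels")
    colsums = signatures.sum(axis=0)
    if not np.allclose(colsums, 1.0, atol=1e-6):
        raise ValueError("signature columns must each sum to 1")
    target = spectrum.fractions.to_numpy(dtype=float)
    weights, _ = nnls(signatures.to_numpy(dtype=float), target)
    total = weights.sum()
    if total > 0:
        weights = weights / total
    return pd.Series(weights, index=signatures.columns, name="weight")


__all__ = [
    "FilterConfig",
    "OBS_COLUMNS",
    "load_variant_blacklist",
    "dedup_mate_overlap",
    "observations_to_frame",
    "build_site_counts",
    "apply_pairwise_variant_exclusion",
    "compute_error_profile",
    "error_free_fraction",
    "position_error_table",
    "fragment_bin_profile",
    "TrinucSpectrum",
    "spectrum_channels",
    "trinuc_spectrum",
    "refit_signatures",
]
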