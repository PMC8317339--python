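"""Synthetic datasets with a ledger of planted truth.

Two generators emulate the statistical structure of UMI-tagged targeted deep
sequencing of paired plasma cfDNA and leucocyte gDNA:

* **counts mode** draws per-position allele-depth tables directly
  (multinomial per position at fixed depth) -- fast enough for
  Monte-Carlo calibration of the group statistics;
* **reads mode** simulates molecules end-to-end: fragments drawn over a
  panel, germline alleles and molecule-level damage applied *before* PCR
  amplification (so lesion-derived errors propagate to whole UMI families
  and survive consensus), zero-truncated-Poisson progeny counts, and
  per-read sequencer miscalls drawn from the base-quality model.  Output is
  either an in-memory observation frame or a coordinate-sorted, indexed BAM
  with RX-tagged UMIs plus FASTA/BED sidecars.

Presets mirror the magnitudes the method was built to detect: a cfDNA-like
group whose only elevation is a uniform (position-independent) C>T / G>A
excess, and a gDNA-like group whose only end effect is a 5x C>A / G>T
multiplier in the first 5 bp of the fragment -- deamination vs
shearing-oxidation, respectively.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .datamodel import ALL_CLASSES, BASES, COMPLEMENT, SampleMeta, collapse_class

_BASE_CODE = {b: i for i, b in enumerate(BASES)}
_CODE_BASE = np.array(list(BASES))


def _rate_key(c) -> str:
    return str(c)


def default_class_rates(base_rate: float = 0.9e-5, **overrides: float) -> dict[str, float]:
    """Uniform per-class rate table with named overrides (e.g. ``C_T=6.9e-5``).

    Override keys use ``_`` for ``>`` (``C_T`` is the C>T class).
    """
    rates = {str(c): base_rate for c in ALL_CLASSES}
    for key, val in overrides.items():
        cls = key.replace("_", ">")
        if cls not in rates:
            raise ValueError(f"unknown substitution class {cls!r}")
        rates[cls] = val
    return rates


@dataclass(frozen=True)
class SimConfig:
    """Fully-specified generative settings for one sample group.

    ``class_rates`` are per-opportunity probabilities that a sequenced base
    whose reference is the class's source base reads as the class's
    alternate base (background, molecule-level in reads mode).
    ``end_effect`` entries ``(class, first_k_bp, multiplier)`` multiply a
    class's rate within ``first_k_bp`` of either fragment end (molecule
    level, applied before amplification).  ``umi_mean_progeny`` is the mean
    of the zero-truncated Poisson family-size distribution; the motivating
    data averaged 2.79 progeny per template.
    """

    class_rates: Mapping[str, float] = field(default_factory=default_class_rates)
    end_effect: tuple[tuple[str, int, float], ...] = ()
    panel_bp: int = 50_000
    chrom: str = "panel1"
    depth: int = 1000                      # counts mode
    germline_het_sites: int = 100
    germline_hom_sites: int = 0
    n_samples: int = 5
    mode: str = "counts"                   # "counts" | "reads"
    # reads mode
    n_fragments: int = 10_000
    fragment_length: int = 167
    read_length: int = 100
    umi_mean_progeny: float = 2.79
    umi_length: int = 8
    pcr_error_rate: float = 0.0
    quality_distribution: tuple[tuple[int, float], ...] = ((37, 1.0),)
    seq_error_rate: float | None = None    # None: derive from base quality

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "reads"):
            raise ValueError(f"mode must be counts or reads, got {self.mode!r}")
        for cls, rate in self.class_rates.items():
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"rate for {cls} out of [0,1]: {rate}")
        for cls, k, mult in self.end_effect:
            if mult < 0 or k < 1:
                raise ValueError(f"invalid end effect ({cls}, {k}, {mult})")
        if self.depth < 1 or self.panel_bp < 1:
            raise ValueError("depth and panel_bp must be >= 1")
        if self.mode == "reads":
            if self.fragment_length < self.read_length:
                raise ValueError("fragment shorter than read length")
            if self.panel_bp <= self.fragment_length:
                raise ValueError("panel shorter than fragment length")
        if self.umi_mean_progeny <= 1.0:
            raise ValueError("umi_mean_progeny must exceed 1 (zero-truncated Poisson)")
        weights = [w for _, w in self.quality_distribution]
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("quality_distribution weights must sum to 1")


# ---------------------------------------------------------------------------
# Presets: the cfDNA-like and gDNA-like worlds differ only in the uniform
# C>T/G>A elevation and the first-5-bp C>A/G>T end effect, respectively.
# Counts-mode totals match the motivating magnitudes (5.7e-5 vs 2.7e-5 at
# uniform base composition); reads-mode presets sit at the top of the
# realistic 1e-5..1e-4 per-class range so that desk-scale fragment numbers
# carry enough error events for the bin statistics.
# ---------------------------------------------------------------------------

def gdna_counts_preset(**overrides) -> SimConfig:
    return SimConfig(class_rates=default_class_rates(0.9e-5), **overrides)


def cfdna_counts_preset(**overrides) -> SimConfig:
    return SimConfig(
        class_rates=default_class_rates(0.9e-5, C_T=6.9e-5, G_A=6.9e-5), **overrides
    )


def gdna_reads_preset(**overrides) -> SimConfig:
    defaults = dict(
        class_rates=default_class_rates(1.0e-4),
        end_effect=(("C>A", 5, 5.0), ("G>T", 5, 5.0)),
        mode="reads",
        fragment_length=450,
        panel_bp=2_000,
        germline_het_sites=0,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


def cfdna_reads_preset(**overrides) -> SimConfig:
    defaults = dict(
        class_rates=default_class_rates(1.0e-4, C_T=3.0e-4, G_A=3.0e-4),
        mode="reads",
        fragment_length=167,
        panel_bp=2_000,
        germline_het_sites=0,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


# ---------------------------------------------------------------------------
# Truth ledger
# ---------------------------------------------------------------------------

@dataclass
class TruthLedger:
    """Everything the generator planted, for use as a test oracle."""

    chrom: str
    reference: str
    configs: dict[str, SimConfig]               # group label -> config
    germline: pd.DataFrame                      # pair_id,pos,ref,alt,genotype,af
    events: pd.DataFrame | None = None          # reads mode per-event records
    fragments: pd.DataFrame | None = None       # reads mode per-fragment records
    seed: int = 0

    def planted_rate(self, group: str, cls: str) -> float:
        return float(self.configs[group].class_rates[cls])

    def expected_total_rate(self, group: str) -> float:
        """Planted total error rate given the realized base composition."""
        codes = np.frombuffer(self.reference.encode(), dtype=np.uint8)
        total = 0.0
        n = len(self.reference)
        for b in BASES:
            f = (codes == ord(b)).sum() / n
            total += f * sum(
                rate for cls, rate in self.configs[group].class_rates.items()
                if cls.startswith(b + ">")
            )
        return total

    def germline_alleles(self, pair_id: str) -> frozenset:
        sub = self.germline[self.germline["pair_id"] == pair_id]
        return frozenset(
            (self.chrom, int(p), a) for p, a in zip(sub["pos"], sub["alt"])
        )


@dataclass
class SimulatedDataset:
    """A paired two-group dataset plus its ledger."""

    samples: list[SampleMeta]
    ledger: TruthLedger
    counts: dict[str, pd.DataFrame] = field(default_factory=dict)
    observations: dict[str, pd.DataFrame] = field(default_factory=dict)
    bam_paths: dict[str, Path] = field(default_factory=dict)
    reference_path: Path | None = None
    panel_path: Path | None = None

    def group_of(self, sample_id: str) -> str:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s.sample_type
        raise KeyError(sample_id)

    def pairs(self) -> dict[str, tuple[str, str]]:
        out: dict[str, dict[str, str]] = {}
        for s in self.samples:
            out.setdefault(s.pair_id, {})[s.sample_type] = s.sample_id
        return {p: (d["cfDNA"], d["gDNA"]) for p, d in out.items()
                if set(d) == {"cfDNA", "gDNA"}}


# ---------------------------------------------------------------------------
# Shared machinery
# ---------------------------------------------------------------------------

def _draw_reference(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.int8)


def _plant_germline(
    rng: np.random.Generator,
    refcodes: np.ndarray,
    n_het: int,
    n_hom: int,
    pair_id: str,
    chrom: str,
) -> pd.DataFrame:
    n_sites = n_het + n_hom
    if n_sites == 0:
        return pd.DataFrame(columns=["pair_id", "chrom", "pos", "ref", "alt",
                                     "genotype", "af"])
    pos = rng.choice(len(refcodes), size=n_sites, replace=False)
    pos.sort()
    alts = (refcodes[pos] + rng.integers(1, 4, size=n_sites)) % 4
    genotype = np.array(["het"] * n_het + ["hom"] * n_hom)
    rng.shuffle(genotype)
    return pd.DataFrame({
        "pair_id": pair_id,
        "chrom": chrom,
        "pos": pos.astype(int),
        "ref": _CODE_BASE[refcodes[pos]],
        "alt": _CODE_BASE[alts],
        "genotype": genotype,
        "af": np.where(genotype == "het", 0.5, 1.0),
    })


def _ztp_lambda(mean: float) -> float:
    """Poisson parameter whose zero-truncated mean equals ``mean``."""
    return brentq(lambda lam: lam / (1.0 - np.exp(-lam)) - mean, 1e-9, 50.0)


def sample_family_sizes(
    rng: np.random.Generator, mean: float, size: int
) -> np.ndarray:
    """Zero-truncated Poisson progeny counts by rejection of zeros."""
    lam = _ztp_lambda(mean)
    out = np.empty(size, dtype=np.int64)
    filled = 0
    while filled < size:
        draw = rng.poisson(lam, size=max(size - filled, 16))
        draw = draw[draw > 0]
        take = min(len(draw), size - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out


def _class_rate_arrays(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-refcode alt-rate matrices (4x4) for interior and end-zone bases."""
    base = np.zeros((4, 4))
    for cls, rate in cfg.class_rates.items():
        r, a = cls.split(">")
        base[_BASE_CODE[r], _BASE_CODE[a]] = rate
    end = base.copy()
    k_values = {k for _, k, _ in cfg.end_effect}
    if len(k_values) > 1:
        raise ValueError("all end effects must share one first_k_bp window")
    k = k_values.pop() if k_values else 0
    for cls, _, mult in cfg.end_effect:
        r, a = cls.split(">")
        end[_BASE_CODE[r], _BASE_CODE[a]] = base[_BASE_CODE[r], _BASE_CODE[a]] * mult
    return base, end, k


# ---------------------------------------------------------------------------
# Counts mode
# ---------------------------------------------------------------------------

def _simulate_sample_counts(
    rng: np.random.Generator,
    refcodes: np.ndarray,
    cfg: SimConfig,
    germline: pd.DataFrame,
) -> pd.DataFrame:
    """One sample's site-count table: multinomial allele depths per position."""
    n = len(refcodes)
    depth = cfg.depth
    counts = np.zeros((n, 4), dtype=np.int64)
    base_rates, _, _ = _class_rate_arrays(cfg)
    for r in range(4):
        rows = np.nonzero(refcodes == r)[0]
        if not len(rows):
            continue
        pvals = base_rates[r].copy()
        pvals[r] = 1.0 - pvals.sum()
        counts[rows] = rng.multinomial(depth, pvals, size=len(rows))
    # germline sites: variant allele replaces its background-error draw
    for row in germline.itertuples():
        r, a = _BASE_CODE[row.ref], _BASE_CODE[row.alt]
        pvals = base_rates[r].copy()
        pvals[a] = row.af
        pvals[r] = 1.0 - pvals.sum()
        counts[row.pos] = rng.multinomial(depth, pvals)
    df = pd.DataFrame(counts, columns=list(BASES))
    df.insert(0, "ref", _CODE_BASE[refcodes])
    df.insert(0, "pos", np.arange(n))
    df.insert(0, "chrom", cfg.chrom)
    df["depth"] = depth
    return df


def simulate_counts(
    cfdna: SimConfig | None,
    gdna: SimConfig | None,
    seed: int,
) -> SimulatedDataset:
    """Paired counts-mode dataset; both groups share one panel and germline.

    Each cfDNA sample ``cf{i}`` is paired with gDNA sample ``g{i}``
    (pair ``P{i}``) and shares that pair's planted germline variants;
    background allele depths are drawn independently per sample.
    Deterministic for a fixed seed.
    """
    configs = {g: c for g, c in (("cfDNA", cfdna), ("gDNA", gdna)) if c is not None}
    if not configs:
        raise ValueError("at least one group config required")
    any_cfg = next(iter(configs.values()))
    for cfg in configs.values():
        if cfg.mode != "counts":
            raise ValueError("simulate_counts requires mode='counts' configs")
        if cfg.panel_bp != any_cfg.panel_bp or cfg.chrom != any_cfg.chrom:
            raise ValueError("group configs must share panel geometry")
    root = np.random.SeedSequence(seed)
    ref_rng, germ_rng, *_ = [np.random.default_rng(s) for s in root.spawn(3)]
    refcodes = _draw_reference(ref_rng, any_cfg.panel_bp)
    n_pairs = max(cfg.n_samples for cfg in configs.values())
    germline_frames = [
        _plant_germline(germ_rng, refcodes, any_cfg.germline_het_sites,
                        any_cfg.germline_hom_sites, f"P{i + 1}", any_cfg.chrom)
        for i in range(n_pairs)
    ]
    germline = (pd.concat(germline_frames, ignore_index=True) if germline_frames
                else _plant_germline(germ_rng, refcodes, 0, 0, "", any_cfg.chrom))
    ledger = TruthLedger(chrom=any_cfg.chrom,
                         reference="".join(_CODE_BASE[refcodes]),
                         configs=configs, germline=germline, seed=seed)
    samples: list[SampleMeta] = []
    counts: dict[str, pd.DataFrame] = {}
    sample_seeds = root.spawn(2 * n_pairs + 4)[4:]
    si = 0
    for group, prefix in (("cfDNA", "cf"), ("gDNA", "g")):
        if group not in configs:
            continue
        cfg = configs[group]
        for i in range(cfg.n_samples):
            sid = f"{prefix}{i + 1}"
            pair = f"P{i + 1}"
            rng = np.random.default_rng(sample_seeds[si]); si += 1
            pair_germ = germline[germline["pair_id"] == pair]
            counts[sid] = _simulate_sample_counts(rng, refcodes, cfg, pair_germ)
            samples.append(SampleMeta(sample_id=sid, subject_id=pair,
                                      sample_type=group, pair_id=pair))
    return SimulatedDataset(samples=samples, ledger=ledger, counts=counts)


# ---------------------------------------------------------------------------
# Reads mode
# ---------------------------------------------------------------------------

def _apply_point_events(
    rng: np.random.Generator,
    mol: np.ndarray,           # (F, L) molecule base codes, modified in place
    prob: np.ndarray,          # (F, L) per-entry event probability
    category: str,
    starts: np.ndarray,
    records: list[dict],
    sample_id: str,
    rate_rows: np.ndarray | None = None,  # (4,4) conditional alt rates, or None=uniform
) -> None:
    hit_f, hit_c = np.nonzero(rng.random(mol.shape) < prob)
    if not len(hit_f):
        return
    cur = mol[hit_f, hit_c]
    alts = np.empty(len(hit_f), dtype=np.int8)
    for r in range(4):
        sel = np.nonzero(cur == r)[0]
        if not len(sel):
            continue
        others = np.array([b for b in range(4) if b != r], dtype=np.int8)
        if rate_rows is None:
            choice = rng.integers(0, 3, size=len(sel))
        else:
            w = rate_rows[r][others.astype(int)]
            if w.sum() <= 0:
                alts[sel] = -1
                continue
            choice = rng.choice(3, size=len(sel), p=w / w.sum())
        alts[sel] = others[choice]
    keep = alts >= 0
    hit_f, hit_c, cur, alts = hit_f[keep], hit_c[keep], cur[keep], alts[keep]
    mol[hit_f, hit_c] = alts
    for f, c, b0, b1 in zip(hit_f, hit_c, cur, alts):
        records.append({
            "sample_id": sample_id, "category": category, "fragment": int(f),
            "pos": int(starts[f] + c), "base_from": BASES[b0], "base_to": BASES[b1],
            "read_row": -1,
        })


def _encode_umis(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    codes = rng.integers(0, 4, size=(n, length))
    return np.array(["".join(_CODE_BASE[row]) for row in codes])


def _simulate_sample_reads(
    rng: np.random.Generator,
    refcodes: np.ndarray,
    cfg: SimConfig,
    germline: pd.DataFrame,
    sample_id: str,
) -> tuple[dict, list[dict]]:
    """Simulate one sample's molecules and progeny reads.

    Returns (arrays, event_records): ``arrays`` holds everything needed to
    build the observation frame or a BAM (per-read windows of base codes,
    qualities, fragment metadata).
    """
    F, L, rl = cfg.n_fragments, cfg.fragment_length, cfg.read_length
    events: list[dict] = []
    starts = rng.integers(0, len(refcodes) - L + 1, size=F)
    starts.sort()
    mol = refcodes[starts[:, None] + np.arange(L)].copy()

    # germline alleles, molecule level (consistent across both read windows)
    for row in germline.itertuples():
        covering = np.nonzero((starts <= row.pos) & (row.pos < starts + L))[0]
        if not len(covering):
            continue
        has_alt = rng.random(len(covering)) < row.af
        mol[covering[has_alt], row.pos - starts[covering[has_alt]]] = _BASE_CODE[row.alt]

    # molecule-level damage, end-zone multiplied; then first-cycle PCR errors
    base_rates, end_rates, k = _class_rate_arrays(cfg)
    total_base = base_rates.sum(axis=1)
    total_end = end_rates.sum(axis=1)
    cols = np.arange(L)
    end_zone = (cols < k) | (cols >= L - k)
    prob = total_base[mol.astype(int)]
    if k:
        prob_end = total_end[mol.astype(int)]
        prob = np.where(end_zone[None, :], prob_end, prob)
        # conditional alt distribution differs in the end zone: split draws
        _apply_point_events(rng, mol, np.where(end_zone[None, :], 0.0, prob),
                            "damage", starts, events, sample_id, base_rates)
        _apply_point_events(rng, mol, np.where(end_zone[None, :], prob, 0.0),
                            "damage", starts, events, sample_id, end_rates)
    else:
        _apply_point_events(rng, mol, prob, "damage", starts, events, sample_id,
                            base_rates)
    if cfg.pcr_error_rate > 0:
        _apply_point_events(rng, mol, np.full(mol.shape, cfg.pcr_error_rate),
                            "pcr", starts, events, sample_id, None)

    # progeny expansion: each family member is one read pair
    fam_sizes = sample_family_sizes(rng, cfg.umi_mean_progeny, F)
    rep = np.repeat(np.arange(F), fam_sizes)
    n_pairs = len(rep)
    left = mol[rep][:, :rl].copy()
    right = mol[rep][:, L - rl:].copy()

    # per-read base qualities and sequencer miscalls (minority events)
    quals, weights = zip(*cfg.quality_distribution)
    if len(quals) == 1:
        q_left = np.full(left.shape, quals[0], dtype=np.int8)
        q_right = np.full(right.shape, quals[0], dtype=np.int8)
    else:
        q_left = rng.choice(quals, size=left.shape, p=weights).astype(np.int8)
        q_right = rng.choice(quals, size=right.shape, p=weights).astype(np.int8)
    for window, q, offset in ((left, q_left, 0), (right, q_right, L - rl)):
        if cfg.seq_error_rate is not None:
            perr = np.full(window.shape, cfg.seq_error_rate)
        else:
            perr = 10.0 ** (-q.astype(float) / 10.0)
        hit_r, hit_c = np.nonzero(rng.random(window.shape) < perr)
        if len(hit_r):
            cur = window[hit_r, hit_c]
            alts = (cur + rng.integers(1, 4, size=len(hit_r))) % 4
            window[hit_r, hit_c] = alts
            for rr, cc, b0, b1 in zip(hit_r, hit_c, cur, alts):
                events.append({
                    "sample_id": sample_id, "category": "seq",
                    "fragment": int(rep[rr]),
                    "pos": int(starts[rep[rr]] + offset + cc),
                    "base_from": BASES[b0], "base_to": BASES[b1],
                    "read_row": int(rr),
                })

    umis = _encode_umis(rng, F, cfg.umi_length)
    r1_is_left = rng.random(F) < 0.5
    arrays = dict(
        starts=starts, fam_sizes=fam_sizes, rep=rep, umis=umis,
        left=left, right=right, q_left=q_left, q_right=q_right,
        r1_is_left=r1_is_left, L=L, rl=rl, F=F, n_pairs=n_pairs,
    )
    fragments = pd.DataFrame({
        "sample_id": sample_id,
        "fragment": np.arange(F),
        "start": starts.astype(np.int64),
        "end": (starts + L).astype(np.int64),
        "umi": umis,
        "strand": np.where(r1_is_left, "+", "-"),
        "family_size": fam_sizes,
    })
    return arrays, events, fragments


def _arrays_to_frame(
    arrays: dict, cfg: SimConfig, refcodes: np.ndarray, lean: bool = False
) -> pd.DataFrame:
    """Flatten per-read windows into the standard observation frame.

    ``lean`` drops the UMI-family columns (not needed for non-consensus
    analyses), roughly halving memory at bin-analysis scale.
    """
    starts, rep = arrays["starts"], arrays["rep"]
    L, rl, n_pairs = arrays["L"], arrays["rl"], arrays["n_pairs"]
    frames = []
    if not lean:
        umi_cats, umi_inv = np.unique(arrays["umis"], return_inverse=True)
    for side, window, q in (("left", arrays["left"], arrays["q_left"]),
                            ("right", arrays["right"], arrays["q_right"])):
        offset = 0 if side == "left" else L - rl
        pos = (starts[rep][:, None] + offset + np.arange(rl)).ravel()
        obs = window.ravel()
        ref = refcodes[pos]
        if side == "left":
            dist = np.tile(np.arange(1, rl + 1), n_pairs)
        else:
            dist = np.tile(np.arange(rl, 0, -1), n_pairs)
        cols = {
            "chrom": pd.Categorical.from_codes(
                np.zeros(len(pos), dtype=np.int8), categories=[cfg.chrom]),
            "pos": pos.astype(np.int32),
            "ref": pd.Categorical.from_codes(ref, categories=list(BASES)),
            "obs": pd.Categorical.from_codes(obs, categories=list(BASES)),
            "qual": q.ravel().astype(np.int16),
            "dist": dist.astype(np.int16),
        }
        if not lean:
            # mate number: R1 is the left read iff r1_is_left for its fragment
            r1_left = arrays["r1_is_left"][rep]
            mate = np.where(r1_left == (side == "left"), 1, 2)
            cols.update({
                "umi": pd.Categorical.from_codes(
                    umi_inv[rep].repeat(rl), categories=list(umi_cats)),
                "fragment_start": starts[rep].repeat(rl).astype(np.int64),
                "fragment_end": (starts[rep] + L).repeat(rl).astype(np.int64),
                "fragment_strand": pd.Categorical.from_codes(
                    np.where(arrays["r1_is_left"][rep], 0, 1).repeat(rl),
                    categories=["+", "-"]),
                "pair_id": np.repeat(np.arange(n_pairs), rl),
                "read_id": np.repeat(np.arange(n_pairs) * 2 + (mate - 1), rl),
            })
        frames.append(pd.DataFrame(cols))
    return pd.concat(frames, ignore_index=True)


def _write_bam(
    arrays: dict, cfg: SimConfig, refcodes: np.ndarray, out_bam: Path, sample_id: str
) -> None:
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": cfg.chrom, "LN": int(len(refcodes))}],
        "RG": [{"ID": sample_id, "SM": sample_id}],
    }
    starts, rep = arrays["starts"], arrays["rep"]
    L, rl = arrays["L"], arrays["rl"]
    tmp = out_bam.with_suffix(".unsorted.bam")
    copy_idx = np.concatenate([np.arange(n) for n in arrays["fam_sizes"]])
    with pysam.AlignmentFile(str(tmp), "wb", header=header) as bam:
        for i in range(arrays["n_pairs"]):
            frag = rep[i]
            name = f"f{frag}c{copy_idx[i]}"
            r1_left = bool(arrays["r1_is_left"][frag])
            for side, window, q in (("left", arrays["left"], arrays["q_left"]),
                                    ("right", arrays["right"], arrays["q_right"])):
                a = pysam.AlignedSegment()
                a.query_name = name
                a.query_sequence = "".join(_CODE_BASE[window[i]])
                a.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(qq + 33) for qq in q[i]))
                a.reference_id = 0
                a.cigarstring = f"{rl}M"
                a.mapping_quality = 60
                is_left = side == "left"
                a.reference_start = int(starts[frag] + (0 if is_left else L - rl))
                a.next_reference_id = 0
                a.next_reference_start = int(starts[frag] + (L - rl if is_left else 0))
                a.template_length = int(L if is_left else -L)
                is_read1 = r1_left == is_left
                a.flag = (
                    pysam.FPAIRED | pysam.FPROPER_PAIR
                    | (pysam.FREAD1 if is_read1 else pysam.FREAD2)
                    | (0 if is_left else pysam.FREVERSE)
                    | (pysam.FMREVERSE if is_left else 0)
                )
                a.set_tag("RX", str(arrays["umis"][frag]))
                a.set_tag("RG", sample_id)
                bam.write(a)
    pysam.sort("-o", str(out_bam), str(tmp))
    Path(tmp).unlink()
    pysam.index(str(out_bam))


def simulate_reads(
    cfdna: SimConfig | None,
    gdna: SimConfig | None,
    seed: int,
    outdir: str | Path | None = None,
    lean_frames: bool = False,
) -> SimulatedDataset:
    """Paired reads-mode dataset: observation frames, or BAMs when ``outdir``.

    With ``outdir`` set, writes one coordinate-sorted indexed BAM per sample
    plus a shared reference FASTA, panel BED and a ledger JSON sidecar, and
    records the paths on the returned dataset; otherwise in-memory
    observation frames (same generative process, same schema the BAM
    streaming path produces) are attached.
    """
    configs = {g: c for g, c in (("cfDNA", cfdna), ("gDNA", gdna)) if c is not None}
    if not configs:
        raise ValueError("at least one group config required")
    any_cfg = next(iter(configs.values()))
    for cfg in configs.values():
        if cfg.mode != "reads":
            raise ValueError("simulate_reads requires mode='reads' configs")
        if cfg.panel_bp != any_cfg.panel_bp or cfg.chrom != any_cfg.chrom:
            raise ValueError("group configs must share panel geometry")
    root = np.random.SeedSequence(seed)
    ref_rng, germ_rng = [np.random.default_rng(s) for s in root.spawn(2)]
    refcodes = _draw_reference(ref_rng, any_cfg.panel_bp)
    n_pairs_group = max(cfg.n_samples for cfg in configs.values())
    germline_frames = [
        _plant_germline(germ_rng, refcodes, any_cfg.germline_het_sites,
                        any_cfg.germline_hom_sites, f"P{i + 1}", any_cfg.chrom)
        for i in range(n_pairs_group)
    ]
    germline = pd.concat(germline_frames, ignore_index=True)
    ledger = TruthLedger(chrom=any_cfg.chrom,
                         reference="".join(_CODE_BASE[refcodes]),
                         configs=configs, germline=germline, seed=seed)
    ds = SimulatedDataset(samples=[], ledger=ledger)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        ref_path = outdir / "reference.fa"
        with open(ref_path, "w") as fh:
            fh.write(f">{any_cfg.chrom}\n")
            seq = ledger.reference
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
        import pysam

        pysam.faidx(str(ref_path))
        panel_path = outdir / "panel.bed"
        panel_path.write_text(f"{any_cfg.chrom}\t0\t{any_cfg.panel_bp}\n")
        ds.reference_path, ds.panel_path = ref_path, panel_path

    all_events: list[pd.DataFrame] = []
    all_fragments: list[pd.DataFrame] = []
    sample_seeds = root.spawn(2 + 2 * n_pairs_group)[2:]
    si = 0
    for group, prefix in (("cfDNA", "cf"), ("gDNA", "g")):
        if group not in configs:
            continue
        cfg = configs[group]
        for i in range(cfg.n_samples):
            sid = f"{prefix}{i + 1}"
            pair = f"P{i + 1}"
            rng = np.random.default_rng(sample_seeds[si]); si += 1
            pair_germ = germline[germline["pair_id"] == pair]
            arrays, events, fragments = _simulate_sample_reads(
                rng, refcodes, cfg, pair_germ, sid)
            all_fragments.append(fragments)
            if events:
                all_events.append(pd.DataFrame(events))
            if outdir is not None:
                bam = Path(outdir) / f"{sid}.bam"
                _write_bam(arrays, cfg, refcodes, bam, sid)
                ds.bam_paths[sid] = bam
            else:
                ds.observations[sid] = _arrays_to_frame(
                    arrays, cfg, refcodes, lean=lean_frames)
            ds.samples.append(SampleMeta(sample_id=sid, subject_id=pair,
                                         sample_type=group, pair_id=pair))
    ledger.events = (pd.concat(all_events, ignore_index=True) if all_events
                     else pd.DataFrame(columns=["sample_id", "category", "fragment",
                                                "pos", "base_from", "base_to",
                                                "read_row"]))
    ledger.fragments = pd.concat(all_fragments, ignore_index=True)
    if outdir is not None:
        sidecar = {
            "seed": seed,
            "chrom": any_cfg.chrom,
            "panel_bp": any_cfg.panel_bp,
            "samples": [s.sample_id for s in ds.samples],
        }
        (Path(outdir) / "ledger.json").write_text(json.dumps(sidecar, indent=2))
    return ds


__all__ = [
    "SimConfig",
    "SimulatedDataset",
    "TruthLedger",
    "default_class_rates",
    "cfdna_counts_preset",
    "gdna_counts_preset",
    "cfdna_reads_preset",
    "gdna_reads_preset",
    "sample_family_sizes",
    "simulate_counts",
    "simulate_reads",
]
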