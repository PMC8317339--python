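"""Shared vocabulary of types for background substitution-error profiling.

Targeted deep sequencing of cell-free DNA (cfDNA) aims to detect somatic
variants at allele fractions far below 1%, where background substitution
errors -- PCR errors, sequencer miscalls and, crucially, errors templated by
DNA lesions such as deaminated cytosine or oxidised guanine -- are the
limiting factor.  Everything downstream counts *substitutions*: a sequenced
base that disagrees with the reference at its position.  A substitution is
classified by its reference and observed base (12 directional classes), and
pairs of reverse-complementary classes are collapsed into 6 strand-symmetric
classes written pyrimidine-first (e.g. ``C:G>T:A`` for C>T together with
G>A), because sequencing cannot tell which strand of the original molecule
carried the lesion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import pandas as pd

BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
PYRIMIDINES = ("C", "T")


class SubstitutionClass(NamedTuple):
    """A directional single-base substitution, e.g. ``C>T``."""

    ref_base: str
    alt_base: str

    def __str__(self) -> str:
        return f"{self.ref_base}>{self.alt_base}"

    @classmethod
    def from_string(cls, s: str) -> "SubstitutionClass":
        ref, _, alt = s.partition(">")
        return make_class(ref, alt)

    def reverse_complement(self) -> "SubstitutionClass":
        return SubstitutionClass(COMPLEMENT[self.ref_base], COMPLEMENT[self.alt_base])


def make_class(ref_base: str, alt_base: str) -> SubstitutionClass:
    """Validated constructor for a substitution class."""
    if ref_base not in BASES or alt_base not in BASES:
        raise ValueError(f"bases must be one of {BASES}, got {ref_base!r}>{alt_base!r}")
    if ref_base == alt_base:
        raise ValueError(f"alt base must differ from ref base ({ref_base!r})")
    return SubstitutionClass(ref_base, alt_base)


#: The 12 directional substitution classes in a fixed display order
#: (pyrimidine-reference classes first, matching strand-collapsed labels).
ALL_CLASSES: tuple[SubstitutionClass, ...] = tuple(
    SubstitutionClass(r, a) for r in ("C", "T", "A", "G") for a in BASES if a != r
)


def collapse_class(c: SubstitutionClass) -> str:
    """Strand-collapsed identifier of a directional class.

    Pairs each class with its reverse-complement partner; the member whose
    reference base is a pyrimidine is written first, so C>T and G>A both map
    to ``C:G>T:A``.
    """
    if c.ref_base not in BASES or c.alt_base not in BASES or c.ref_base == c.alt_base:
        raise ValueError(f"invalid substitution class {c!r}")
    pyr = c if c.ref_base in PYRIMIDINES else c.reverse_complement()
    return (
        f"{pyr.ref_base}:{COMPLEMENT[pyr.ref_base]}>"
        f"{pyr.alt_base}:{COMPLEMENT[pyr.alt_base]}"
    )


#: The 6 strand-collapsed class labels in display order.
COLLAPSED_CLASSES: tuple[str, ...] = tuple(
    dict.fromkeys(collapse_class(c) for c in ALL_CLASSES)
)


@dataclass(frozen=True)
class SampleMeta:
    """Identity and pairing of one sequencing library.

    ``pair_id`` links a plasma cfDNA sample to its matched peripheral-blood
    leucocyte gDNA sample from the same subject; the germline-variant filter
    is evaluated jointly on the pair.  ``replicate_id`` labels technical
    duplicates of the same library.
    """

    sample_id: str
    subject_id: str
    sample_type: str  # "cfDNA" | "gDNA"
    pair_id: str
    replicate_id: str = "1"

    def __post_init__(self) -> None:
        if self.sample_type not in ("cfDNA", "gDNA"):
            raise ValueError(f"sample_type must be cfDNA or gDNA, got {self.sample_type!r}")


def validate_pairing(samples: Iterable[SampleMeta]) -> dict[str, tuple[SampleMeta, SampleMeta]]:
    """Check that every pair_id links exactly one cfDNA and one gDNA sample.

    Returns ``{pair_id: (cfdna_sample, gdna_sample)}``; raises ``ValueError``
    on incomplete or overloaded pairs.
    """
    by_pair: dict[str, dict[str, SampleMeta]] = {}
    for s in samples:
        slot = by_pair.setdefault(s.pair_id, {})
        if s.sample_type in slot:
            raise ValueError(f"pair {s.pair_id!r} has more than one {s.sample_type} sample")
        slot[s.sample_type] = s
    out = {}
    for pair_id, slot in by_pair.items():
        if set(slot) != {"cfDNA", "gDNA"}:
            missing = {"cfDNA", "gDNA"} - set(slot)
            raise ValueError(f"pair {pair_id!r} is missing its {'/'.join(sorted(missing))} member")
        out[pair_id] = (slot["cfDNA"], slot["gDNA"])
    return out


class BaseObservation(NamedTuple):
    """One sequenced base at one genomic position.

    ``dist_from_breakpoint`` is the 1-based offset of the base from its
    read's 5' end in original sequencing orientation.  A read's 5' end
    coincides with a true fragment breakpoint both for native cfDNA
    fragments and for sonicated gDNA, so this distance indexes proximity to
    physical DNA ends, where shearing-induced lesions concentrate.
    """

    chrom: str
    pos: int  # 0-based
    ref_base: str
    obs_base: str
    base_quality: int
    read_id: str
    umi: str
    fragment_start: int  # 0-based half-open
    fragment_end: int
    dist_from_breakpoint: int  # >= 1
    fragment_strand: str = "+"  # strand of R1; part of the UMI-family key


# ---------------------------------------------------------------------------
# SiteCounts: the per-position pileup summary all rates derive from.
# Represented as a pandas DataFrame with columns
#   chrom, pos (0-based), ref, A, C, G, T, depth
# where depth = A+C+G+T (ambiguous bases are dropped from both numerator and
# denominator before this table is built).
# ---------------------------------------------------------------------------

SITE_COUNT_COLUMNS = ["chrom", "pos", "ref", "A", "C", "G", "T", "depth"]


def empty_site_counts() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype="int64" if c not in ("chrom", "ref") else "object")
                         for c in SITE_COUNT_COLUMNS})


def validate_site_counts(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SITE_COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"site-counts table is missing columns {missing}")
    base_sum = df[list(BASES)].sum(axis=1)
    if not (base_sum == df["depth"]).all():
        raise ValueError("allele depths must sum to depth (N bases are dropped upstream)")
    if (df[list(BASES)].to_numpy() < 0).any():
        raise ValueError("negative allele depth")
    return df


@dataclass
class ErrorProfile:
    """Per-sample background substitution error rates.

    Rates are errors per *eligible* sequenced base: the count of non-reference
    bases of each class divided by the number of sequenced bases whose
    reference base offers the opportunity for that class
    (``eligible_bases[ref]``).  ``rate_total`` divides all errors by all
    eligible bases.  A ``total``-denominator variant (every class divided by
    all sequenced bases) is available via :meth:`rates_total_denominator`.
    """

    sample_id: str
    error_counts: dict[SubstitutionClass, int]
    eligible_bases: dict[str, int]
    n_eligible_positions: int = 0

    @property
    def rates(self) -> dict[SubstitutionClass, float]:
        out = {}
        for c in ALL_CLASSES:
            denom = self.eligible_bases.get(c.ref_base, 0)
            out[c] = (self.error_counts.get(c, 0) / denom) if denom > 0 else float("nan")
        return out

    def rates_total_denominator(self) -> dict[SubstitutionClass, float]:
        denom = sum(self.eligible_bases.values())
        if denom == 0:
            return {c: float("nan") for c in ALL_CLASSES}
        return {c: self.error_counts.get(c, 0) / denom for c in ALL_CLASSES}

    @property
    def collapsed_rates(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for label in COLLAPSED_CLASSES:
            members = [c for c in ALL_CLASSES if collapse_class(c) == label]
            num = sum(self.error_counts.get(c, 0) for c in members)
            den = sum(self.eligible_bases.get(c.ref_base, 0) for c in members)
            out[label] = num / den if den > 0 else float("nan")
        return out

    @property
    def total_rate(self) -> float:
        den = sum(self.eligible_bases.values())
        return sum(self.error_counts.values()) / den if den > 0 else float("nan")

    # -- serialization ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rates = self.rates
        rows = [
            {
                "class": str(c),
                "collapsed": collapse_class(c),
                "errors": self.error_counts.get(c, 0),
                "eligible_bases": self.eligible_bases.get(c.ref_base, 0),
                "rate": rates[c],
            }
            for c in ALL_CLASSES
        ]
        for label, rate in self.collapsed_rates.items():
            members = [c for c in ALL_CLASSES if collapse_class(c) == label]
            rows.append(
                {
                    "class": label,
                    "collapsed": label,
                    "errors": sum(self.error_counts.get(c, 0) for c in members),
                    "eligible_bases": sum(self.eligible_bases.get(c.ref_base, 0) for c in members),
                    "rate": rate,
                }
            )
        rows.append(
            {
                "class": "total",
                "collapsed": "total",
                "errors": sum(self.error_counts.values()),
                "eligible_bases": sum(self.eligible_bases.values()),
                "rate": self.total_rate,
            }
        )
        return pd.DataFrame(rows)

    def write(self, tsv_path: str | Path, metadata: Mapping | None = None) -> None:
        """Write the 12 + 6 + total table as TSV plus a JSON sidecar."""
        tsv_path = Path(tsv_path)
        self.to_frame().to_csv(tsv_path, sep="\t", index=False)
        sidecar = {
            "sample_id": self.sample_id,
            "error_counts": {str(c): n for c, n in self.error_counts.items()},
            "eligible_bases": dict(self.eligible_bases),
            "n_eligible_positions": self.n_eligible_positions,
        }
        if metadata:
            sidecar["metadata"] = dict(metadata)
        tsv_path.with_suffix(tsv_path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2, sort_keys=True)
        )

    @classmethod
    def read(cls, tsv_path: str | Path) -> "ErrorProfile":
        sidecar = json.loads(Path(str(tsv_path) + ".json").read_text())
        return cls(
            sample_id=sidecar["sample_id"],
            error_counts={SubstitutionClass.from_string(k): v
                          for k, v in sidecar["error_counts"].items()},
            eligible_bases=sidecar["eligible_bases"],
            n_eligible_positions=sidecar.get("n_eligible_positions", 0),
        )


@dataclass
class FragmentBinProfile:
    """Per-class error rates in ten 5-bp bins from the DNA breakpoint.

    Bin ``b`` covers read positions ``5(b-1)+1 .. 5b`` counted from the
    read's 5' end; bases beyond 50 bp are not binned.  Tables are 10x12
    (bins x directional classes) with counts and eligible-base denominators
    kept so rates always recompute exactly.
    """

    sample_id: str
    bin_counts: pd.DataFrame  # index bins 1..10, columns str(class)
    bin_eligible_bases: pd.DataFrame  # index bins 1..10, columns ref base

    @property
    def bin_rates(self) -> pd.DataFrame:
        rates = {}
        for c in ALL_CLASSES:
            denom = self.bin_eligible_bases[c.ref_base]
            rates[str(c)] = self.bin_counts[str(c)] / denom.where(denom > 0)
        return pd.DataFrame(rates, index=self.bin_counts.index)

    def total_bin_rates(self) -> pd.Series:
        return self.bin_counts.sum(axis=1) / self.bin_eligible_bases.sum(axis=1)

    def collapsed_bin_rates(self) -> pd.DataFrame:
        """Per-bin rates of the 6 strand-collapsed classes (pooled counts)."""
        out = {}
        for label in COLLAPSED_CLASSES:
            members = [c for c in ALL_CLASSES if collapse_class(c) == label]
            num = sum(self.bin_counts[str(c)] for c in members)
            den = sum(self.bin_eligible_bases[c.ref_base] for c in members)
            out[label] = num / den.where(den > 0)
        return pd.DataFrame(out, index=self.bin_counts.index)

    def write(self, tsv_path: str | Path, metadata: Mapping | None = None) -> None:
        tsv_path = Path(tsv_path)
        self.bin_rates.rename_axis("bin").to_csv(tsv_path, sep="\t")
        sidecar = {
            "sample_id": self.sample_id,
            "bin_counts": self.bin_counts.to_dict(),
            "bin_eligible_bases": self.bin_eligible_bases.to_dict(),
        }
        if metadata:
            sidecar["metadata"] = dict(metadata)
        tsv_path.with_suffix(tsv_path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2, sort_keys=True)
        )


__all__ = [
    "BASES",
    "COMPLEMENT",
    "ALL_CLASSES",
    "COLLAPSED_CLASSES",
    "SITE_COUNT_COLUMNS",
    "SubstitutionClass",
    "make_class",
    "collapse_class",
    "SampleMeta",
    "validate_pairing",
    "BaseObservation",
    "empty_site_counts",
    "validate_site_counts",
    "ErrorProfile",
    "FragmentBinProfile",
]
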