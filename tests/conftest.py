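"""Shared fixtures: toy BAM construction and small simulated datasets."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import pytest

from bgerr.datamodel import BaseObservation


@pytest.fixture
def bam_factory(tmp_path):
    """Factory writing a small indexed BAM + FASTA + BED from read specs.

    Each read spec is a dict with keys: name, start, seq, and optionally
    qual (list of phreds), flag fields (reverse, paired, proper_pair, read2,
    duplicate, secondary, unmapped), mapq, tlen, mate_start, umi.
    """

    def make(reads, refseq, chrom="chr1", panel=None):
        ref_path = tmp_path / "ref.fa"
        with open(ref_path, "w") as fh:
            fh.write(f">{chrom}\n{refseq}\n")
        pysam.faidx(str(ref_path))
        bed_path = tmp_path / "panel.bed"
        intervals = panel or [(0, len(refseq))]
        bed_path.write_text(
            "".join(f"{chrom}\t{s}\t{e}\n" for s, e in intervals))
        header = {"HD": {"VN": "1.6", "SO": "coordinate"},
                  "SQ": [{"SN": chrom, "LN": len(refseq)}]}
        tmp_bam = tmp_path / "toy.unsorted.bam"
        with pysam.AlignmentFile(str(tmp_bam), "wb", header=header) as bam:
            for spec in reads:
                a = pysam.AlignedSegment()
                a.query_name = spec["name"]
                a.query_sequence = spec["seq"]
                quals = spec.get("qual", [37] * len(spec["seq"]))
                a.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in quals))
                a.reference_id = 0
                a.reference_start = spec["start"]
                a.cigarstring = spec.get("cigar", f"{len(spec['seq'])}M")
                a.mapping_quality = spec.get("mapq", 60)
                flag = 0
                if spec.get("paired"):
                    flag |= pysam.FPAIRED
                    if spec.get("proper_pair", True):
                        flag |= pysam.FPROPER_PAIR
                    flag |= pysam.FREAD2 if spec.get("read2") else pysam.FREAD1
                    a.next_reference_id = 0
                    a.next_reference_start = spec.get("mate_start", spec["start"])
                    a.template_length = spec.get("tlen", 0)
                if spec.get("reverse"):
                    flag |= pysam.FREVERSE
                if spec.get("mate_reverse"):
                    flag |= pysam.FMREVERSE
                if spec.get("duplicate"):
                    flag |= pysam.FDUP
                if spec.get("secondary"):
                    flag |= pysam.FSECONDARY
                if spec.get("unmapped"):
                    flag |= pysam.FUNMAP
                a.flag = flag
                a.set_tag("RX", spec.get("umi", "ACGT"))
                bam.write(a)
        bam_path = tmp_path / "toy.bam"
        pysam.sort("-o", str(bam_path), str(tmp_bam))
        pysam.index(str(bam_path))
        return bam_path, bed_path, ref_path

    return make


def obs(chrom="chr1", pos=10, ref="C", base="C", qual=37, read_id="r1",
        umi="AAAA", frag=(0, 50), dist=5, strand="+"):
    """Terse BaseObservation builder for unit tests."""
    return BaseObservation(
        chrom=chrom, pos=pos, ref_base=ref, obs_base=base, base_quality=qual,
        read_id=read_id, umi=umi, fragment_start=frag[0], fragment_end=frag[1],
        dist_from_breakpoint=dist, fragment_strand=strand)


@pytest.fixture
def make_obs():
    return obs


@pytest.fixture(scope="session")
def small_counts_dataset():
    """3+3 paired counts-mode dataset on a 4 kb panel (session-cached)."""
    from bgerr.synthetic import cfdna_counts_preset, gdna_counts_preset, simulate_counts

    cf = cfdna_counts_preset(panel_bp=4000, n_samples=3, germline_het_sites=20)
    g = gdna_counts_preset(panel_bp=4000, n_samples=3, germline_het_sites=20)
    return simulate_counts(cf, g, seed=11)


@pytest.fixture(scope="session")
def small_reads_dataset():
    """1+1 paired reads-mode dataset with full observation frames."""
    from bgerr.synthetic import cfdna_reads_preset, gdna_reads_preset, simulate_reads

    cf = cfdna_reads_preset(n_fragments=800, n_samples=1, germline_het_sites=5)
    g = gdna_reads_preset(n_fragments=800, n_samples=1, germline_het_sites=5)
    return simulate_reads(cf, g, seed=13)
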