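"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest


@dataclass
class ToyRead:
    """A read specified in read orientation (5'->3' of the sequenced strand)."""

    ref: str        # aligned reference bases, read orientation
    query: str      # read bases, read orientation
    is_reverse: bool = False


COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(COMP)[::-1]


def tally_by_hand(reads, p_max=20):
    """Independent brute-force tally of terminal counts and lengths.

    Works base by base on the read-orientation strings, assigning each base
    to whichever terminus it is nearer (ties to 5'), entirely separately
    from the alignment parser.
    """
    ref5 = {p: {b: 0 for b in "ACGT"} for p in range(1, p_max + 1)}
    ref3 = {p: {b: 0 for b in "ACGT"} for p in range(1, p_max + 1)}
    sub5 = {p: {} for p in range(1, p_max + 1)}
    sub3 = {p: {} for p in range(1, p_max + 1)}
    lengths = []
    for read in reads:
        n = len(read.query)
        lengths.append(n)
        for i in range(n):
            dist5 = i + 1
            dist3 = n - i
            if dist5 <= dist3:
                refs, subs, pos = ref5, sub5, dist5
            else:
                refs, subs, pos = ref3, sub3, dist3
            if pos > p_max:
                continue
            r, q = read.ref[i], read.query[i]
            if r not in "ACGT" or q not in "ACGT":
                continue
            refs[pos][r] += 1
            if q != r:
                key = f"{r}>{q}"
                subs[pos][key] = subs[pos].get(key, 0) + 1
    return ref5, sub5, ref3, sub3, lengths


def md_tag(ref_fwd: str, seq: str) -> str:
    parts, run = [], 0
    for r, q in zip(ref_fwd, seq):
        if r == q:
            run += 1
        else:
            parts.append(str(run))
            parts.append(r)
            run = 0
    parts.append(str(run))
    return "".join(parts)


def write_sam(path, reads, n_unmapped=0, ref_name="chr1"):
    """Write toy reads as a SAM file with correct MD tags.

    Reverse-strand reads are stored reference-forward with flag 16, exactly
    as an aligner would emit them.
    """
    gap = 5
    pos = 0
    lines = []
    for i, read in enumerate(reads):
        if read.is_reverse:
            ref_fwd, seq, flag = revcomp(read.ref), revcomp(read.query), 16
        else:
            ref_fwd, seq, flag = read.ref, read.query, 0
        lines.append(
            f"r{i + 1}\t{flag}\t{ref_name}\t{pos + 1}\t60\t{len(seq)}M\t"
            f"*\t0\t0\t{seq}\t*\tMD:Z:{md_tag(ref_fwd, seq)}"
        )
        pos += len(seq) + gap
    for j in range(n_unmapped):
        lines.append(f"u{j + 1}\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\t*")
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{ref_name}\tLN:{max(pos, 4)}\n")
        fh.write("\n".join(lines) + ("\n" if lines else ""))
    return path


def random_reads(rng, n_reads, min_len=8, max_len=60, mismatch_p=0.08):
    reads = []
    for _ in range(n_reads):
        n = int(rng.integers(min_len, max_len + 1))
        ref = "".join(rng.choice(list("ACGT"), size=n))
        query = list(ref)
        for i in range(n):
            if rng.random() < mismatch_p:
                query[i] = rng.choice([b for b in "ACGT" if b != ref[i]])
        reads.append(ToyRead(ref, "".join(query),
                             is_reverse=bool(rng.random() < 0.5)))
    return reads


@pytest.fixture
def toy_reads():
    """Three forward reads with hand-placed mismatches (incl. C>T at 5' p1)."""
    return [
        ToyRead(ref="CATTGACCGGTAAGCT", query="TATTGACCGGTAAGCT"),   # C>T at p1
        ToyRead(ref="GGATCCATTAAGGCTA", query="GGATCCATTAAGGCTA"),   # clean
        ToyRead(ref="ACGTACGTACGTACGA", query="ACGTACGTACGTACGG"),   # A>G at 3' p1
    ]


@pytest.fixture
def toy_sam(tmp_path, toy_reads):
    return write_sam(tmp_path / "toy.sam", toy_reads)
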