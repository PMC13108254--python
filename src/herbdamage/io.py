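"""Ingestion of aligned reads, damage-count tables and sample metadata.

This module turns upstream artefacts (merged single-end alignments in SAM/BAM,
or pre-tallied mapDamage-style count tables) into the in-memory containers the
damage metrics consume:

* :class:`AlignmentSummary` -- read counts for the endogenous fraction,
* :class:`FragmentLengthHistogram` -- merged-read length distribution,
* :class:`TerminalSubstitutionCounts` -- position-wise reference-base and
  substitution counts at the 5' and 3' read termini,

bundled per sample into :class:`DamageTables`.

Conventions
-----------
Positions are 1-based and counted inward from each terminus in *read
orientation*: reverse-strand records are complemented and index-flipped before
tallying, so that 5' C>T and 3' G>A keep their post-mortem deamination
meaning.  Only the first ``max_terminal_positions`` (default 20) positions are
stored.  A base in a read shorter than twice that window is assigned to the
terminus it is nearer to (ties go to 5') so that no base is counted twice.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
#: The 12 substitution types, reference base > read base.
SUBSTITUTION_TYPES = tuple(
    f"{r}>{q}" for r in BASES for q in BASES if r != q
)
_SUB_INDEX = {s: i for i, s in enumerate(SUBSTITUTION_TYPES)}
#: Deamination-driven types excluded from the divergence baseline.
DEAMINATION_TYPES = ("C>T", "G>A")

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

DEFAULT_TERMINAL_POSITIONS = 20


class FormatError(ValueError):
    """A damage-table or metadata file does not match the declared dialect."""


@dataclass(frozen=True)
class AlignmentSummary:
    """Read counting for one library.

    ``total_reads`` counts every primary record in the stream (mapped or not)
    after upstream trimming/merging; ``mapped_reads`` counts primary mapped
    non-duplicate records.
    """

    sample_id: str
    total_reads: int
    mapped_reads: int

    def __post_init__(self) -> None:
        if not 0 <= self.mapped_reads <= self.total_reads:
            raise ValueError(
                f"invalid read counts for {self.sample_id}: "
                f"0 <= {self.mapped_reads} <= {self.total_reads} violated"
            )


def endogenous_fraction(summary: AlignmentSummary) -> float:
    """Fraction of post-trimming reads that mapped (endogenous DNA proxy).

    Raises
    ------
    ValueError
        If ``total_reads`` is zero (the fraction is undefined).
    """
    if summary.total_reads == 0:
        raise ValueError(
            f"endogenous fraction undefined for {summary.sample_id}: "
            "total_reads is 0"
        )
    return summary.mapped_reads / summary.total_reads


class FragmentLengthHistogram(Counter):
    """Mapping fragment length (bp) -> occurrence count."""

    def n_fragments(self) -> int:
        return sum(self.values())

    def validate(self) -> None:
        for length, count in self.items():
            if length < 1 or count < 0:
                raise ValueError(
                    f"invalid histogram cell length={length} count={count}"
                )


@dataclass
class TerminalSubstitutionCounts:
    """Position-wise base and substitution counts at one read terminus.

    ``ref_counts[p-1, i]`` is the number of aligned reference bases
    ``BASES[i]`` observed at 1-based position ``p`` from the terminus;
    ``sub_counts[p-1, j]`` the number of ``SUBSTITUTION_TYPES[j]`` events.
    """

    terminus: str  # "5p" or "3p"
    ref_counts: np.ndarray
    sub_counts: np.ndarray

    @classmethod
    def zeros(cls, terminus: str, n_positions: int = DEFAULT_TERMINAL_POSITIONS):
        return cls(
            terminus=terminus,
            ref_counts=np.zeros((n_positions, 4), dtype=np.int64),
            sub_counts=np.zeros((n_positions, 12), dtype=np.int64),
        )

    @property
    def n_positions(self) -> int:
        return self.ref_counts.shape[0]

    def ref_count(self, position: int, base: str) -> int:
        return int(self.ref_counts[position - 1, _BASE_INDEX[base]])

    def sub_count(self, position: int, subst: str) -> int:
        return int(self.sub_counts[position - 1, _SUB_INDEX[subst]])

    def validate(self) -> None:
        if self.terminus not in ("5p", "3p"):
            raise ValueError(f"unknown terminus {self.terminus!r}")
        if (self.ref_counts < 0).any() or (self.sub_counts < 0).any():
            raise ValueError("negative counts in substitution table")
        # substitutions from a base cannot exceed that base's reference count
        for j, sub in enumerate(SUBSTITUTION_TYPES):
            i = _BASE_INDEX[sub[0]]
            if (self.sub_counts[:, j] > self.ref_counts[:, i]).any():
                raise ValueError(
                    f"{sub} counts exceed reference {sub[0]} counts "
                    f"({self.terminus})"
                )


@dataclass
class DamageTables:
    """All per-sample raw counts downstream metrics are computed from."""

    sample_id: str
    summary: AlignmentSummary
    length_histogram: FragmentLengthHistogram
    five_prime: TerminalSubstitutionCounts
    three_prime: TerminalSubstitutionCounts

    def validate(self) -> None:
        self.length_histogram.validate()
        self.five_prime.validate()
        self.three_prime.validate()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DamageTables):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and self.summary == other.summary
            and dict(self.length_histogram) == dict(other.length_histogram)
            and np.array_equal(self.five_prime.ref_counts, other.five_prime.ref_counts)
            and np.array_equal(self.five_prime.sub_counts, other.five_prime.sub_counts)
            and np.array_equal(self.three_prime.ref_counts, other.three_prime.ref_counts)
            and np.array_equal(self.three_prime.sub_counts, other.three_prime.sub_counts)
        )


@dataclass(frozen=True)
class SampleMetadata:
    """Passport information for one specimen."""

    sample_id: str
    species: str
    genus: str
    collection_year: int
    herbarium: str = ""
    latitude: float | None = None
    longitude: float | None = None
    temperature: float | None = None
    precipitation: float | None = None

    def age(self, reference_year: int) -> int:
        age = reference_year - self.collection_year
        if age <= 0:
            raise ValueError(
                f"{self.sample_id}: collection_year {self.collection_year} "
                f"not before reference_year {reference_year}"
            )
        return age


# ---------------------------------------------------------------------------
# alignment parsing
# ---------------------------------------------------------------------------

def parse_alignments(
    source,
    sample_id: str | None = None,
    max_terminal_positions: int = DEFAULT_TERMINAL_POSITIONS,
) -> DamageTables:
    """Tally damage counts from a stream of merged single-end alignments.

    Parameters
    ----------
    source
        Path to a SAM/BAM file, an open :class:`pysam.AlignmentFile`, or any
        iterable of :class:`pysam.AlignedSegment`.
    sample_id
        Identifier recorded in the output; defaults to the file stem.
    max_terminal_positions
        Window (bp) tallied inward from each terminus.

    Notes
    -----
    Secondary and supplementary records are ignored entirely; duplicates are
    counted into ``total_reads`` but never tallied (deduplication is assumed
    upstream); unmapped records count only into ``total_reads``.  Substitution
    context comes from ``get_aligned_pairs(with_seq=True)`` and therefore
    needs an MD tag (or attached reference); mapped records without one keep
    their fragment length but contribute no substitution counts, with a
    logged warning.
    """
    close = False
    if isinstance(source, (str, Path)):
        if sample_id is None:
            sample_id = Path(source).stem
        source = pysam.AlignmentFile(str(source), check_sq=False)
        close = True
    elif isinstance(source, pysam.AlignmentFile):
        if sample_id is None:
            sample_id = Path(source.filename.decode()).stem
    if sample_id is None:
        sample_id = "sample"

    hist = FragmentLengthHistogram()
    five = TerminalSubstitutionCounts.zeros("5p", max_terminal_positions)
    three = TerminalSubstitutionCounts.zeros("3p", max_terminal_positions)
    total = mapped = 0
    try:
        for read in source:
            if read.is_secondary or read.is_supplementary:
                continue
            total += 1
            if read.is_duplicate or read.is_unmapped:
                continue
            mapped += 1
            seq = read.query_sequence
            if seq is None:
                logger.warning(
                    "%s: mapped record %s has no sequence; skipped",
                    sample_id, read.query_name,
                )
                continue
            length = len(seq)
            hist[length] += 1
            try:
                pairs = read.get_aligned_pairs(with_seq=True)
            except ValueError:
                logger.warning(
                    "%s: record %s lacks MD tag/reference context; "
                    "substitutions not tallied", sample_id, read.query_name,
                )
                continue
            _tally_pairs(
                pairs, seq, length, read.is_reverse,
                five, three, max_terminal_positions,
            )
    finally:
        if close:
            source.close()

    return DamageTables(
        sample_id=sample_id,
        summary=AlignmentSummary(sample_id, total, mapped),
        length_histogram=hist,
        five_prime=five,
        three_prime=three,
    )


def _tally_pairs(pairs, seq, length, is_reverse, five, three, p_max):
    for qpos, rpos, rbase in pairs:
        if qpos is None or rpos is None or rbase is None:
            # deletion / insertion / soft clip: no aligned reference base
            continue
        qbase = seq[qpos]
        if is_reverse:
            read_index = length - 1 - qpos
            rbase = rbase.translate(_COMPLEMENT)
            qbase = qbase.translate(_COMPLEMENT)
        else:
            read_index = qpos
        rbase = rbase.upper()
        qbase = qbase.upper()
        if rbase not in _BASE_INDEX or qbase not in _BASE_INDEX:
            continue
        p5 = read_index + 1
        p3 = length - read_index
        if p5 <= p3:
            table, pos = five, p5
        else:
            table, pos = three, p3
        if pos > p_max:
            continue
        table.ref_counts[pos - 1, _BASE_INDEX[rbase]] += 1
        if qbase != rbase:
            table.sub_counts[pos - 1, _SUB_INDEX[f"{rbase}>{qbase}"]] += 1


# ---------------------------------------------------------------------------
# damage-table dialect (mapDamage-compatible)
# ---------------------------------------------------------------------------

_MISINC_COLUMNS = ["End", "Pos", *BASES, *SUBSTITUTION_TYPES]
_LENGTH_COLUMNS = ["Length", "Occurrences"]

MISINCORPORATION_FILE = "misincorporation.txt"
LENGTH_FILE = "lgdistribution.txt"


def write_damage_tables(tables: DamageTables, destination) -> None:
    """Write ``tables`` to ``destination`` (a directory) in the tab-separated
    misincorporation / length-distribution dialect.

    Output is bit-stable for fixed input (sorted rows, no timestamps).
    """
    destination = Path(destination)
    destination.mkdir(parents=True, exist_ok=True)
    header = (
        f"# sample_id={tables.sample_id}\t"
        f"total_reads={tables.summary.total_reads}\t"
        f"mapped_reads={tables.summary.mapped_reads}\n"
    )

    rows = []
    for end, tab in (("5p", tables.five_prime), ("3p", tables.three_prime)):
        for p in range(1, tab.n_positions + 1):
            rows.append(
                [end, p, *tab.ref_counts[p - 1], *tab.sub_counts[p - 1]]
            )
    misinc = pd.DataFrame(rows, columns=_MISINC_COLUMNS)
    with open(destination / MISINCORPORATION_FILE, "w") as fh:
        fh.write(header)
        misinc.to_csv(fh, sep="\t", index=False)

    lengths = sorted(tables.length_histogram.items())
    lg = pd.DataFrame(lengths, columns=_LENGTH_COLUMNS)
    with open(destination / LENGTH_FILE, "w") as fh:
        fh.write(header)
        lg.to_csv(fh, sep="\t", index=False)


def _read_header_metadata(path: Path) -> dict:
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for token in line[1:].strip().split("\t"):
                if "=" in token:
                    key, value = token.split("=", 1)
                    meta[key.strip()] = value.strip()
    return meta


def read_damage_tables(source, sample_id: str | None = None) -> DamageTables:
    """Read damage tables from a directory in the declared dialect.

    Both the pre-summed form and the strand-split form (an optional ``Std``
    column with ``+``/``-`` rows, already in read orientation as upstream
    damage profilers emit them) are accepted; strand-split counts are summed.
    """
    source = Path(source)
    mis_path = source / MISINCORPORATION_FILE
    lg_path = source / LENGTH_FILE
    for path in (mis_path, lg_path):
        if not path.exists():
            raise FormatError(f"missing damage-table file: {path}")

    meta = _read_header_metadata(mis_path)
    if sample_id is None:
        sample_id = meta.get("sample_id", source.name)

    misinc = pd.read_csv(mis_path, sep="\t", comment="#")
    required = [c for c in _MISINC_COLUMNS if c not in ("End", "Pos")]
    for col in ["End", "Pos", *required]:
        if col not in misinc.columns:
            raise FormatError(f"misincorporation table missing column {col!r}")
    if (misinc[required] < 0).to_numpy().any():
        raise FormatError("negative counts in misincorporation table")
    if "Std" in misinc.columns:
        misinc = misinc.groupby(["End", "Pos"], as_index=False)[required].sum()

    n_positions = int(misinc["Pos"].max()) if len(misinc) else DEFAULT_TERMINAL_POSITIONS
    tabs = {}
    for end in ("5p", "3p"):
        tab = TerminalSubstitutionCounts.zeros(end, n_positions)
        block = misinc[misinc["End"] == end]
        for _, row in block.iterrows():
            p = int(row["Pos"])
            tab.ref_counts[p - 1] = [row[b] for b in BASES]
            tab.sub_counts[p - 1] = [row[s] for s in SUBSTITUTION_TYPES]
        tabs[end] = tab

    lg = pd.read_csv(lg_path, sep="\t", comment="#")
    for col in _LENGTH_COLUMNS:
        if col not in lg.columns:
            raise FormatError(f"length-distribution table missing column {col!r}")
    if len(lg) and (lg["Occurrences"] < 0).any():
        raise FormatError("negative counts in length-distribution table")
    if "Std" in lg.columns:
        lg = lg.groupby("Length", as_index=False)["Occurrences"].sum()
    hist = FragmentLengthHistogram(
        {int(r.Length): int(r.Occurrences) for r in lg.itertuples() if r.Occurrences}
    )

    total = int(meta.get("total_reads", hist.n_fragments()))
    mapped = int(meta.get("mapped_reads", hist.n_fragments()))
    return DamageTables(
        sample_id=sample_id,
        summary=AlignmentSummary(sample_id, total, mapped),
        length_histogram=hist,
        five_prime=tabs["5p"],
        three_prime=tabs["3p"],
    )


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

METADATA_COLUMNS = [
    "sample_id", "species", "genus", "collection_year", "herbarium",
    "latitude", "longitude", "temperature", "precipitation",
]
_REQUIRED_METADATA = ["sample_id", "species", "genus", "collection_year"]


def read_metadata(path) -> pd.DataFrame:
    """Read the sample-metadata TSV (blank cells = missing)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    for col in _REQUIRED_METADATA:
        if col not in df.columns:
            raise FormatError(f"metadata missing required column {col!r}")
    for col in METADATA_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df["collection_year"] = df["collection_year"].astype(int)
    return df[METADATA_COLUMNS]


def write_metadata(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def add_age(df: pd.DataFrame, reference_year: int) -> pd.DataFrame:
    """Append an ``age`` column (years before ``reference_year``)."""
    out = df.copy()
    out["age"] = reference_year - out["collection_year"]
    if (out["age"] <= 0).any():
        bad = out.loc[out["age"] <= 0, "sample_id"].tolist()
        raise ValueError(f"non-positive ages for samples {bad}")
    return out
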