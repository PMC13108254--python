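"""Synthetic herbarium-cohort generator with recorded ground truth.

Generates per-sample damage tables with the statistical structure the
analysis assumes, so every pipeline stage can be exercised at desk scale:

* fragment lengths follow a truncated geometric law -- the discrete
  exponential implied by independent per-bond breakage with probability
  per site λ = k · age (optionally plus noise);
* terminal C>T frequencies decay exponentially into the read,
  δ(p) = A · exp(-r (p - 1)) + c, with the amplitude A depending on genus,
  age and collection-site temperature, mirrored as G>A at the 3' end
  (double-stranded library convention);
* all 12 substitution types additionally receive a uniform baseline b,
  emulating sample-reference divergence plus sequencing error;
* endogenous fractions are Beta-distributed and independent of age;
* climate covariates are genus-structured (temperate vs tropical genus
  means) so the genus-climate confounding seen in real herbarium cohorts
  is reproduced by design.

Every draw comes from one seeded generator, so a config plus seed fully
determines the output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .io import (
    BASES,
    SUBSTITUTION_TYPES,
    _BASE_INDEX,
    _SUB_INDEX,
    AlignmentSummary,
    DamageTables,
    FragmentLengthHistogram,
    TerminalSubstitutionCounts,
    write_damage_tables,
    write_metadata,
)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Decay rates reported for herbarium material (per site per year), used as
#: the default simulation truth.
K_HORDEUM = 2.64e-4
K_ORYZA = 1.79e-4
K_OVERALL = 2.08e-4


@dataclass(frozen=True)
class GenusConfig:
    """Per-genus simulation truth."""

    n_samples: int
    k: float                      # decay rate, per site per year
    age_range: tuple[int, int]    # years
    alpha: float                  # deamination amplitude intercept
    beta_age: float               # amplitude change per year of age
    temperature_mean: float       # deg C at collection sites
    temperature_sd: float
    precipitation_mean: float     # mm
    precipitation_sd: float
    baseline: float = 0.006       # divergence + error substitution rate
    beta_temperature: float | None = None  # overrides the global coefficient


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation truth; defaults emulate a two-genus
    temperate/tropical herbarium study."""

    genera: dict[str, GenusConfig] = field(default_factory=lambda: {
        "Hordeum": GenusConfig(
            n_samples=211, k=K_HORDEUM, age_range=(10, 205),
            alpha=0.002, beta_age=2.5e-5,
            temperature_mean=12.0, temperature_sd=5.0,
            precipitation_mean=600.0, precipitation_sd=200.0,
            baseline=0.0055,
        ),
        "Oryza": GenusConfig(
            n_samples=245, k=K_ORYZA, age_range=(15, 225),
            alpha=0.004, beta_age=6.0e-5,
            temperature_mean=25.0, temperature_sd=4.0,
            precipitation_mean=1800.0, precipitation_sd=600.0,
            baseline=0.0078,
        ),
    })
    reference_year: int = 2026
    length_range: tuple[int, int] = (30, 150)
    reads_range: tuple[int, int] = (20_000, 20_000)  # mapped reads per sample
    beta_temperature: float = 1.0e-4  # amplitude per deg C
    positional_rate: float = 0.35     # r, per position
    offset: float = 0.001             # c, asymptotic terminal excess
    endogenous_beta: tuple[float, float] = (8.0, 2.0)
    lambda_noise_sd: float = 0.0
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    terminal_positions: int = 20
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid length_range {self.length_range}")
        if abs(sum(self.base_composition) - 1.0) > 1e-9:
            raise ValueError("base_composition must sum to 1")
        for name, g in self.genera.items():
            if g.k <= 0:
                raise ValueError(f"{name}: k must be positive")
            beta_t = g.beta_temperature if g.beta_temperature is not None \
                else self.beta_temperature
            # worst-case amplitude bound (5 sd temperature excursion)
            a_max = (g.alpha + g.beta_age * g.age_range[1]
                     + max(beta_t, 0.0) * (g.temperature_mean + 5 * g.temperature_sd))
            if a_max + self.offset + g.baseline > 1.0:
                raise ValueError(
                    f"{name}: amplitude + offset + baseline can exceed 1 "
                    f"(bound {a_max + self.offset + g.baseline:.3f})"
                )
            if not 0 <= g.baseline <= 1:
                raise ValueError(f"{name}: baseline outside [0, 1]")


@dataclass
class TruthRecord:
    """Ground truth for one simulated sample."""

    sample_id: str
    genus: str
    age: int
    temperature: float
    precipitation: float
    lam_true: float
    amplitude_true: float
    f_ct1_true: float   # δ(1) + baseline
    baseline_true: float
    endogenous_true: float


@dataclass
class SimulatedRead:
    """One rendered read (read orientation) for SAM emission."""

    ref_bases: str
    query: str
    is_reverse: bool

    @property
    def length(self) -> int:
        return len(self.query)


def _truncated_geometric(rng, lam, lo, hi, size):
    """Sample lengths with P(L) proportional to exp(-lam * L) on [lo, hi]."""
    w = math.exp(-lam)
    span = hi - lo
    u = rng.random(size)
    t = 1.0 - u * (1.0 - w ** (span + 1))
    j = np.floor(np.log(t) / math.log(w)).astype(np.int64)
    return lo + np.clip(j, 0, span)


def _coverage(hist_counts, lengths, p_max):
    """Numbers of reads whose 5'/3' windows reach each position.

    A base at 1-based read position i belongs to the 5' window iff
    i <= ceil(L / 2) (ties to 5'), so position p is covered at 5' by reads
    with L >= 2p - 1 and at 3' by reads with L >= 2p.
    """
    cover5 = np.array([
        int(hist_counts[lengths >= 2 * p - 1].sum()) for p in range(1, p_max + 1)
    ])
    cover3 = np.array([
        int(hist_counts[lengths >= 2 * p].sum()) for p in range(1, p_max + 1)
    ])
    return cover5, cover3


def _delta_profile(amplitude, rate, offset, baseline, p_max):
    p = np.arange(1, p_max + 1)
    delta = amplitude * np.exp(-rate * (p - 1)) + offset
    return np.clip(delta, 0.0, 1.0 - baseline)


def simulate_sample(
    sample_id: str,
    genus: str,
    gcfg: GenusConfig,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    keep_reads: bool = False,
):
    """Simulate one library; returns (metadata dict, DamageTables, TruthRecord,
    reads or None)."""
    lo_a, hi_a = gcfg.age_range
    age = int(rng.integers(lo_a, hi_a + 1))
    temperature = float(rng.normal(gcfg.temperature_mean, gcfg.temperature_sd))
    precipitation = float(max(0.0, rng.normal(
        gcfg.precipitation_mean, gcfg.precipitation_sd)))
    lam = gcfg.k * age
    if cfg.lambda_noise_sd > 0:
        lam += float(rng.normal(0.0, cfg.lambda_noise_sd))
    lam = max(lam, 1e-6)

    beta_t = gcfg.beta_temperature if gcfg.beta_temperature is not None \
        else cfg.beta_temperature
    amplitude = max(0.0, gcfg.alpha + gcfg.beta_age * age + beta_t * temperature)
    delta = _delta_profile(amplitude, cfg.positional_rate, cfg.offset,
                           gcfg.baseline, cfg.terminal_positions)

    endogenous = float(rng.beta(*cfg.endogenous_beta))
    mapped = int(rng.integers(cfg.reads_range[0], cfg.reads_range[1] + 1))
    total = max(mapped, int(round(mapped / max(endogenous, 1e-6))))

    lmin, lmax = cfg.length_range
    lengths = _truncated_geometric(rng, lam, lmin, lmax, mapped)
    hist = FragmentLengthHistogram(
        dict(zip(*map(list, np.unique(lengths, return_counts=True))))
    )

    p_max = cfg.terminal_positions
    five = TerminalSubstitutionCounts.zeros("5p", p_max)
    three = TerminalSubstitutionCounts.zeros("3p", p_max)
    reads = None
    if keep_reads:
        reads = _simulate_reads(
            lengths, delta, gcfg.baseline, cfg, rng, five, three,
        )
    else:
        uniq = np.arange(lmin, lmax + 1)
        counts = np.array([hist.get(int(L), 0) for L in uniq])
        cover5, cover3 = _coverage(counts, uniq, p_max)
        comp = np.asarray(cfg.base_composition)
        src_idx = np.array([_BASE_INDEX[s[0]] for s in SUBSTITUTION_TYPES])
        for tab, cover, hot in ((five, cover5, "C>T"), (three, cover3, "G>A")):
            ref = rng.multinomial(cover, comp)          # (p_max, 4)
            tab.ref_counts[:, :] = ref
            n_src = ref[:, src_idx]                     # (p_max, 12)
            prob = np.full((p_max, 12), gcfg.baseline)
            prob[:, _SUB_INDEX[hot]] = np.minimum(
                delta + gcfg.baseline, 1.0)
            tab.sub_counts[:, :] = rng.binomial(n_src, prob)

    tables = DamageTables(
        sample_id=sample_id,
        summary=AlignmentSummary(sample_id, total, mapped),
        length_histogram=hist,
        five_prime=five,
        three_prime=three,
    )
    meta = {
        "sample_id": sample_id,
        "species": f"{genus} synthetica",
        "genus": genus,
        "collection_year": cfg.reference_year - age,
        "herbarium": "SYN",
        "latitude": np.nan,
        "longitude": np.nan,
        "temperature": temperature,
        "precipitation": precipitation,
    }
    truth = TruthRecord(
        sample_id=sample_id, genus=genus, age=age,
        temperature=temperature, precipitation=precipitation,
        lam_true=lam, amplitude_true=amplitude,
        f_ct1_true=float(min(delta[0] + gcfg.baseline, 1.0)),
        baseline_true=gcfg.baseline,
        endogenous_true=endogenous,
    )
    return meta, tables, truth, reads


def _simulate_reads(lengths, delta, baseline, cfg, rng, five, three,
                    reverse_fraction=0.3):
    """Per-read simulation path: renders reads and tallies tables at once,
    so planted counts equal the tallied tables by construction."""
    comp = np.asarray(cfg.base_composition)
    p_max = cfg.terminal_positions
    reads: list[SimulatedRead] = []
    for L in lengths:
        L = int(L)
        ref = rng.choice(len(BASES), size=L, p=comp)
        ref_bases = [BASES[i] for i in ref]
        query = list(ref_bases)
        for idx in range(L):
            p5 = idx + 1
            p3 = L - idx
            if p5 <= p3:
                tab, pos, hot = five, p5, "C>T"
            else:
                tab, pos, hot = three, p3, "G>A"
            if pos > p_max:
                continue
            rbase = ref_bases[idx]
            tab.ref_counts[pos - 1, _BASE_INDEX[rbase]] += 1
            # choose at most one substitution event per base
            probs = {}
            for sub in SUBSTITUTION_TYPES:
                if sub[0] != rbase:
                    continue
                probs[sub] = baseline + (
                    delta[pos - 1] if sub == hot else 0.0)
            u = rng.random()
            acc = 0.0
            for sub, pr in probs.items():
                acc += pr
                if u < acc:
                    query[idx] = sub[2]
                    tab.sub_counts[pos - 1, _SUB_INDEX[sub]] += 1
                    break
        reads.append(SimulatedRead(
            ref_bases="".join(ref_bases),
            query="".join(query),
            is_reverse=bool(rng.random() < reverse_fraction),
        ))
    return reads


def simulate_cohort(config: SimulationConfig, keep_reads: bool = False):
    """Simulate a full cohort.

    Returns ``(metadata, tables, truth)`` -- a metadata DataFrame, a list of
    :class:`DamageTables` and a truth DataFrame -- or with
    ``keep_reads=True`` an extra dict mapping sample id to the rendered
    reads.  Fully reproducible from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    meta_rows, all_tables, truth_rows = [], [], []
    reads_by_sample: dict[str, list[SimulatedRead]] = {}
    counter = 0
    for genus in config.genera:
        gcfg = config.genera[genus]
        for _ in range(gcfg.n_samples):
            counter += 1
            sid = f"SYN{counter:04d}"
            meta, tables, truth, reads = simulate_sample(
                sid, genus, gcfg, config, rng, keep_reads=keep_reads,
            )
            meta_rows.append(meta)
            all_tables.append(tables)
            truth_rows.append(asdict(truth))
            if reads is not None:
                reads_by_sample[sid] = reads
    metadata = pd.DataFrame(meta_rows)
    truth = pd.DataFrame(truth_rows)
    if keep_reads:
        return metadata, all_tables, truth, reads_by_sample
    return metadata, all_tables, truth


# ---------------------------------------------------------------------------
# emission
# ---------------------------------------------------------------------------

def reads_to_sam(reads: list[SimulatedRead], path, sample_id: str,
                 n_unmapped: int = 0) -> None:
    """Render simulated reads as single-end SAM records on one synthetic
    contig, with CIGAR/MD consistent with the planted mismatches.

    Reverse-strand reads are stored reference-forward (sequence
    reverse-complemented, flag 16), as in a real alignment.
    """
    gap = 10
    offsets = []
    pos = 0
    for read in reads:
        offsets.append(pos)
        pos += read.length + gap
    ref_len = max(pos, 1)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:synthetic_ref\tLN:{ref_len}\n")
        for i, read in enumerate(reads):
            if read.is_reverse:
                ref_fwd = read.ref_bases.translate(_COMPLEMENT)[::-1]
                seq = read.query.translate(_COMPLEMENT)[::-1]
                flag = 16
            else:
                ref_fwd = read.ref_bases
                seq = read.query
                flag = 0
            md = _md_tag(ref_fwd, seq)
            fh.write(
                f"{sample_id}_r{i + 1}\t{flag}\tsynthetic_ref\t"
                f"{offsets[i] + 1}\t60\t{read.length}M\t*\t0\t0\t"
                f"{seq}\t*\tMD:Z:{md}\tNM:i:{_n_mismatches(ref_fwd, seq)}\n"
            )
        for j in range(n_unmapped):
            fh.write(
                f"{sample_id}_u{j + 1}\t4\t*\t0\t0\t*\t*\t0\t0\t"
                f"ACGT\t*\n"
            )


def _md_tag(ref: str, query: str) -> str:
    parts = []
    run = 0
    for r, q in zip(ref, query):
        if r == q:
            run += 1
        else:
            parts.append(str(run))
            parts.append(r)
            run = 0
    parts.append(str(run))
    return "".join(parts)


def _n_mismatches(ref: str, query: str) -> int:
    return sum(r != q for r, q in zip(ref, query))


def emit_sample_data(
    tables: DamageTables,
    destination,
    reads: list[SimulatedRead] | None = None,
) -> None:
    """Write one sample's damage tables (and optionally a toy SAM rendering
    of its reads) under ``destination``."""
    from pathlib import Path

    destination = Path(destination)
    write_damage_tables(tables, destination)
    if reads is not None:
        n_unmapped = tables.summary.total_reads - tables.summary.mapped_reads
        reads_to_sam(
            reads, destination / f"{tables.sample_id}.sam",
            tables.sample_id, n_unmapped=n_unmapped,
        )


def emit_cohort(metadata, all_tables, truth, destination,
                reads_by_sample=None) -> None:
    """Write a whole simulated cohort: metadata TSV, truth TSV and one
    damage-table directory per sample."""
    from pathlib import Path

    destination = Path(destination)
    destination.mkdir(parents=True, exist_ok=True)
    write_metadata(metadata, destination / "metadata.tsv")
    truth.to_csv(destination / "truth.tsv", sep="\t", index=False)
    for tables in all_tables:
        reads = (reads_by_sample or {}).get(tables.sample_id)
        emit_sample_data(tables, destination / tables.sample_id, reads=reads)
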