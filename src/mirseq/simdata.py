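"""Deterministic synthetic data for pipeline validation.

Three generators, each seeded and reproducible byte-for-byte:

* a toy genome with planted miRNA hairpins (known and novel), tRNA and
  rRNA decoy loci — hairpins are built with an exact reverse-complement
  stem so the discovery criteria are satisfiable by construction;
* replicated two-condition small-RNA read libraries whose per-miRNA
  counts are negative-binomial (variance mu + alpha*mu^2) with planted
  fold changes, 3' adapter read-through and Phred quality decay;
* a patient cohort with wild-type / mutant-p53 groups, planted log2
  expression shifts, node-status associations and exponential survival
  with planted hazard ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import BedInterval, phred_to_string, revcomp, write_fastq

DNA = np.array(list("ACGT"))
_COMP = str.maketrans("ACGT", "TGCA")

# Sanger/Illumina small-RNA style 3' adapter
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


# --------------------------------------------------------------------------
# toy genome
# --------------------------------------------------------------------------

@dataclass
class ToyGenomeSpec:
    """Layout of the synthetic genome and its planted features."""
    n_chromosomes: int = 1
    chrom_length: int = 50000
    n_known_mirnas: int = 10
    n_novel_mirnas: int = 1
    n_trna_decoys: int = 2
    n_rrna_decoys: int = 2
    stem_length: int = 30
    loop_length: int = 8
    mature_length: int = 22
    rng_seed: int = 0

    def validate(self) -> None:
        if self.mature_length > self.stem_length:
            raise ValueError("mature_length must fit within one stem arm")
        for name in ("n_chromosomes", "chrom_length", "stem_length",
                     "loop_length", "mature_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class Feature:
    """A planted locus, BED-style 0-based half-open genome coordinates."""
    feature_id: str
    ftype: str          # known_mirna | novel_mirna | trna | rrna
    chrom: str
    start: int
    end: int
    strand: str
    mature_start: int = -1   # genome coords of the mature arm (miRNAs)
    mature_end: int = -1

    def to_bed(self) -> BedInterval:
        return BedInterval(self.chrom, self.start, self.end,
                           self.feature_id, 0.0, self.strand)


@dataclass
class ToyGenome:
    genome: dict[str, str]
    features: list[Feature]
    mature: dict[str, str]       # known mature miRNAs (sense strand)
    precursors: dict[str, str]   # known precursor hairpins
    novel_mature: dict[str, str]     # planted novel matures (truth only)
    trna: dict[str, str]
    rrna: dict[str, str]

    def known_mirna_bed(self) -> list[BedInterval]:
        return [f.to_bed() for f in self.features
                if f.ftype == "known_mirna"]

    def feature_bed(self) -> list[BedInterval]:
        return [f.to_bed() for f in self.features]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(DNA[rng.integers(0, 4, n)])


def _build_hairpin(rng: np.random.Generator, spec: ToyGenomeSpec,
                   ) -> tuple[str, int, int]:
    """Random hairpin; returns (sequence, mature_offset, mature_len).

    5' arm is random, 3' arm is its exact reverse complement, the loop
    is random; the mature sits at the outer end of a randomly chosen arm
    so that all its pairing partners lie on the opposite arm.
    """
    arm = _random_seq(rng, spec.stem_length)
    loop = _random_seq(rng, spec.loop_length)
    seq = list(arm + loop + revcomp(arm))
    n = len(seq)
    if rng.random() < 0.5:
        mat_off = 0                                   # 5' arm
    else:
        mat_off = n - spec.mature_length              # 3' arm
    # Turn a few G:C pairs of the non-mature arm into G:U wobbles
    # (C -> T on the non-mature strand): the fold keeps its stem but the
    # two arms stop being exact reverse complements of each other, so
    # mature reads map uniquely (real precursor stems are imperfect).
    partners = [n - 1 - k for k in
                range(mat_off, mat_off + spec.mature_length)]
    candidates = [p for p in partners if seq[p] == "C"]
    rng.shuffle(candidates)
    for p in candidates[:3]:
        seq[p] = "T"
    return "".join(seq), mat_off, spec.mature_length


def generate_toy_genome(spec: ToyGenomeSpec) -> ToyGenome:
    """Plant non-overlapping features into random chromosomes."""
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    chroms = {f"chr{i + 1}": list(_random_seq(rng, spec.chrom_length))
              for i in range(spec.n_chromosomes)}
    chrom_names = list(chroms)

    plan: list[tuple[str, int]] = (
        [("known_mirna", i) for i in range(spec.n_known_mirnas)]
        + [("novel_mirna", i) for i in range(spec.n_novel_mirnas)]
        + [("trna", i) for i in range(spec.n_trna_decoys)]
        + [("rrna", i) for i in range(spec.n_rrna_decoys)])

    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    features: list[Feature] = []
    mature: dict[str, str] = {}
    precursors: dict[str, str] = {}
    novel_mature: dict[str, str] = {}
    trna: dict[str, str] = {}
    rrna: dict[str, str] = {}

    pad = 150  # keep planted loci clear of each other and chromosome ends

    def place(length: int) -> tuple[str, int]:
        for _ in range(2000):
            chrom = chrom_names[rng.integers(0, len(chrom_names))]
            if spec.chrom_length < length + 2 * pad:
                continue
            start = int(rng.integers(pad, spec.chrom_length - length - pad))
            if all(start >= e + pad or start + length + pad <= s
                   for s, e in occupied[chrom]):
                occupied[chrom].append((start, start + length))
                return chrom, start
        raise ValueError(
            "cannot place planted features without overlap: "
            f"{spec.n_known_mirnas} known + {spec.n_novel_mirnas} novel "
            f"miRNAs, {spec.n_trna_decoys} tRNA, {spec.n_rrna_decoys} rRNA "
            f"decoys in {spec.n_chromosomes} x {spec.chrom_length} nt")

    for ftype, idx in plan:
        if ftype in ("known_mirna", "novel_mirna"):
            seq, mat_off, mat_len = _build_hairpin(rng, spec)
            chrom, start = place(len(seq))
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                genome_piece = seq
                mstart = start + mat_off
            else:
                genome_piece = revcomp(seq)
                mstart = start + len(seq) - mat_off - mat_len
            chroms[chrom][start:start + len(seq)] = list(genome_piece)
            name = (f"mir-{idx + 1:03d}" if ftype == "known_mirna"
                    else f"novel-mir-{idx + 1}")
            features.append(Feature(name, ftype, chrom, start,
                                    start + len(seq), strand,
                                    mstart, mstart + mat_len))
            mat_seq = seq[mat_off:mat_off + mat_len]
            if ftype == "known_mirna":
                mature[name] = mat_seq
                precursors[name] = seq
            else:
                novel_mature[name] = mat_seq
        else:
            length = 75 if ftype == "trna" else 120
            seq = _random_seq(rng, length)
            chrom, start = place(length)
            chroms[chrom][start:start + length] = list(seq)
            name = f"{ftype}-{idx + 1}"
            features.append(Feature(name, ftype, chrom, start,
                                    start + length, "+"))
            (trna if ftype == "trna" else rrna)[name] = seq

    genome = {c: "".join(v) for c, v in chroms.items()}
    return ToyGenome(genome, features, mature, precursors,
                     novel_mature, trna, rrna)


# --------------------------------------------------------------------------
# read simulation
# --------------------------------------------------------------------------

@dataclass
class ReadSimSpec:
    """Composition and noise model of the simulated libraries."""
    libraries: list[tuple[str, int]] = field(
        default_factory=lambda: [("control", 1), ("control", 2),
                                 ("mutant", 1), ("mutant", 2)])
    mean_depth: int = 5000
    mirna_fraction: float = 0.77
    trna_fraction: float = 0.04
    rrna_fraction: float = 0.005
    adapter_dimer_fraction: float = 0.002
    genomic_noise_fraction: float = 0.01   # intergenic reads; the rest of
    # the non-class mass is unmappable junk (library artifacts)
    nb_dispersion: float = 0.05
    planted_fold_changes: dict[str, float] = field(default_factory=dict)
    fold_change_condition: str = "mutant"   # condition carrying the effect
    adapter_sequence: str = DEFAULT_ADAPTER
    quality_decay: float = 0.30             # Phred units per base, 3'-ward
    instrument_length: int = 35
    novel_read_mean: float = 3.0            # expected novel-arm reads/library
    rng_seed: int = 0

    def validate(self) -> None:
        fracs = (self.mirna_fraction, self.trna_fraction,
                 self.rrna_fraction, self.adapter_dimer_fraction,
                 self.genomic_noise_fraction)
        if any(f < 0 or f > 1 for f in fracs) or sum(fracs) > 1:
            raise ValueError("class fractions must lie in [0,1] and sum <= 1")
        if any(fc <= 0 for fc in self.planted_fold_changes.values()):
            raise ValueError("fold changes must be positive")
        if self.mean_depth <= 0:
            raise ValueError("depth must be positive")


def _make_quals(rng: np.random.Generator, n: int, decay: float) -> str:
    q = 38.0 - decay * np.arange(n) + rng.normal(0, 1.5, n)
    return phred_to_string(np.clip(np.rint(q), 2, 40).astype(int))


def simulate_reads(toy: ToyGenome, spec: ReadSimSpec, outdir: str | Path
                   ) -> tuple[dict[str, Path], pd.DataFrame]:
    """Write one FASTQ per library; return paths and the truth table.

    The truth table holds one row per (library, read class, feature) with
    the realized read count — class counts sum to the library total.
    """
    spec.validate()
    if not any(toy.genome.values()):
        raise ValueError("empty genome")
    if spec.mirna_fraction > 0 and not toy.mature:
        raise ValueError("mirna_fraction > 0 but no planted miRNAs")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.rng_seed)

    mir_ids = sorted(toy.mature)
    # baseline abundance weights shared by all libraries; log-normal
    # across miRNAs, matching the long-tailed abundance of real
    # small-RNA libraries
    if mir_ids:
        weights = 10.0 ** rng.normal(0.0, 1.0, len(mir_ids))
        # planted effects need detectable baseline expression: lift
        # fold-change carriers to at least the median abundance
        med = float(np.median(weights))
        for i, fid in enumerate(mir_ids):
            if fid in spec.planted_fold_changes:
                weights[i] = max(weights[i], med)
        weights /= weights.sum()
    else:
        weights = []
    chrom_names = sorted(toy.genome)
    feat_by_id = {f.feature_id: f for f in toy.features}

    def mirna_read(fid: str, jitter: int) -> str:
        """Mature read with 3' jitter taken from genomic context."""
        f = feat_by_id[fid]
        if f.strand == "+":
            s, e = f.mature_start, min(f.mature_end + max(jitter, 0), f.end)
            if jitter < 0:
                e = max(f.mature_start + 17, f.mature_end + jitter)
            return toy.genome[f.chrom][s:e]
        s, e = max(f.mature_start - max(jitter, 0), f.start), f.mature_end
        if jitter < 0:
            s = min(f.mature_end - 17, f.mature_start - jitter)
        return revcomp(toy.genome[f.chrom][s:e])

    paths: dict[str, Path] = {}
    truth_rows = []
    for cond, rep in spec.libraries:
        lib = f"{cond}_rep{rep}"
        records: list[tuple[str, str, str]] = []
        serial = 0

        def emit(insert: str, kind: str, feat: str) -> None:
            nonlocal serial
            read = (insert + spec.adapter_sequence)[:spec.instrument_length]
            qual = _make_quals(rng, len(read), spec.quality_decay)
            records.append((f"{lib}:r{serial:06d} kind={kind} feat={feat}",
                            read, qual))
            serial += 1

        # per-miRNA NB counts
        lib_counts: dict[str, int] = {}
        for fid, w in zip(mir_ids, weights):
            mu = spec.mean_depth * spec.mirna_fraction * w
            if cond == spec.fold_change_condition:
                mu *= spec.planted_fold_changes.get(fid, 1.0)
            if spec.nb_dispersion < 1e-9:
                c = rng.poisson(mu)
            else:
                r = 1.0 / spec.nb_dispersion
                c = rng.negative_binomial(r, r / (r + mu))
            lib_counts[fid] = int(c)
            for _ in range(int(c)):
                emit(mirna_read(fid, int(rng.integers(-2, 3))), "mirna", fid)
            truth_rows.append((lib, cond, rep, "mirna", fid, int(c)))

        # novel-arm reads (not in the mature reference)
        for fid in sorted(toy.novel_mature):
            c = int(rng.poisson(spec.novel_read_mean))
            for _ in range(c):
                emit(mirna_read(fid, int(rng.integers(-1, 2))), "novel", fid)
            truth_rows.append((lib, cond, rep, "novel", fid, c))

        # decoys, adapter dimers, genomic noise
        n_mirna = sum(lib_counts.values())
        denom = spec.mirna_fraction if spec.mirna_fraction > 0 else 1.0
        n_total_target = max(n_mirna, int(round(n_mirna / denom))) \
            if mir_ids else spec.mean_depth
        for kind, frac, refs in (
                ("trna", spec.trna_fraction, toy.trna),
                ("rrna", spec.rrna_fraction, toy.rrna)):
            n_kind = rng.binomial(n_total_target, frac) if refs else 0
            names = sorted(refs)
            for _ in range(int(n_kind)):
                name = names[rng.integers(0, len(names))]
                seq = refs[name]
                ln = int(rng.integers(17, 31))
                start = int(rng.integers(0, len(seq) - ln + 1))
                emit(seq[start:start + ln], kind, name)
            truth_rows.append((lib, cond, rep, kind, "*", int(n_kind)))

        n_ad = int(rng.binomial(n_total_target,
                                spec.adapter_dimer_fraction))
        for _ in range(n_ad):
            emit("", "adapter_dimer", "*")
        truth_rows.append((lib, cond, rep, "adapter_dimer", "*", n_ad))

        n_gnoise = int(rng.binomial(n_total_target,
                                    spec.genomic_noise_fraction))
        for _ in range(n_gnoise):
            chrom = chrom_names[rng.integers(0, len(chrom_names))]
            ln = int(rng.integers(17, 31))
            start = int(rng.integers(0, len(toy.genome[chrom]) - ln + 1))
            frag = toy.genome[chrom][start:start + ln]
            if rng.random() < 0.5:
                frag = revcomp(frag)
            emit(frag, "noise", "*")
        truth_rows.append((lib, cond, rep, "noise", "*", n_gnoise))

        used = (spec.mirna_fraction + spec.trna_fraction
                + spec.rrna_fraction + spec.adapter_dimer_fraction
                + spec.genomic_noise_fraction)
        n_junk = int(rng.binomial(n_total_target, max(0.0, 1.0 - used)))
        for _ in range(n_junk):
            emit(_random_seq(rng, int(rng.integers(17, 31))), "junk", "*")
        truth_rows.append((lib, cond, rep, "junk", "*", n_junk))

        path = outdir / f"{lib}.fastq"
        write_fastq(records, path)
        paths[lib] = path

    truth = pd.DataFrame(truth_rows, columns=[
        "library", "condition", "replicate", "kind", "feature", "count"])
    return paths, truth


def truth_mirna_counts(truth: pd.DataFrame) -> pd.DataFrame:
    """miRNA x library matrix of realized simulated counts."""
    sub = truth[truth["kind"] == "mirna"]
    return sub.pivot_table(index="feature", columns="library",
                           values="count", aggfunc="sum", fill_value=0)


# --------------------------------------------------------------------------
# 3'UTR set with planted target sites
# --------------------------------------------------------------------------

@dataclass
class UTRSimSpec:
    """Synthetic 3'UTR sequences with planted miRNA target sites."""
    n_targets_per_mirna: int = 5
    n_background: int = 20
    utr_length: int = 300
    rng_seed: int = 0


def generate_utrs(mirnas: dict[str, str], spec: UTRSimSpec
                  ) -> tuple[dict[str, str], pd.DataFrame]:
    """UTR set where each miRNA gets full-complement planted sites.

    Returns (transcript id -> sequence, truth table of planted sites).
    Planted sites are the exact reverse complement of the full mature
    sequence, so they satisfy both the alignment-score and the duplex
    energy criteria by construction.
    """
    rng = np.random.default_rng(spec.rng_seed)
    utrs: dict[str, str] = {}
    rows = []
    serial = 0
    for mir_id in sorted(mirnas):
        site = revcomp(mirnas[mir_id].replace("U", "T"))
        for _ in range(spec.n_targets_per_mirna):
            serial += 1
            tid = f"tx-{serial:04d}"
            seq = _random_seq(rng, spec.utr_length)
            pos = int(rng.integers(10, spec.utr_length - len(site) - 10))
            seq = seq[:pos] + site + seq[pos + len(site):]
            utrs[tid] = seq
            rows.append((tid, mir_id, pos, pos + len(site)))
    for _ in range(spec.n_background):
        serial += 1
        utrs[f"tx-{serial:04d}"] = _random_seq(rng, spec.utr_length)
    truth = pd.DataFrame(rows, columns=["transcript", "mirna",
                                        "site_start", "site_end"])
    return utrs, truth


# --------------------------------------------------------------------------
# cohort simulation
# --------------------------------------------------------------------------

@dataclass
class CohortSimSpec:
    """Planted structure of the synthetic patient cohort."""
    n_patients: int = 200
    mutant_fraction: float = 0.35
    truncating_fraction: float = 0.15    # of mutant patients
    n_background_mirnas: int = 20
    planted_mirna_shifts: dict[str, float] = field(default_factory=dict)
    node_positive_rate: float = 0.38
    node_unknown_rate: float = 0.03
    node_effect_mirnas: dict[str, float] = field(default_factory=dict)
    survival_hazard_ratios: dict[str, float] = field(default_factory=dict)
    censoring_rate: float = 0.3
    expression_sd: float = 1.0           # log2 within-group SD
    baseline_median_months: float = 36.0
    rng_seed: int = 0

    def validate(self) -> None:
        for name in ("mutant_fraction", "truncating_fraction",
                     "node_positive_rate", "node_unknown_rate",
                     "censoring_rate"):
            v = getattr(self, name)
            if v < 0 or v > 1:
                raise ValueError(f"{name} must lie in [0,1]")
        if any(hr <= 0 for hr in self.survival_hazard_ratios.values()):
            raise ValueError("hazard ratios must be positive")
        if self.n_patients < 8:
            raise ValueError("need at least 8 patients")

    def mirna_ids(self) -> list[str]:
        planted = (set(self.planted_mirna_shifts)
                   | set(self.node_effect_mirnas)
                   | set(self.survival_hazard_ratios))
        background = [f"mir-bg-{i + 1:02d}"
                      for i in range(self.n_background_mirnas)]
        return sorted(planted) + background


def simulate_cohort(spec: CohortSimSpec) -> pd.DataFrame:
    """Patient table with p53/node status, survival and expression.

    Expression columns hold linear normalized values (RPM-like, 2**log2).
    Survival is exponential; each miRNA with a planted hazard ratio
    multiplies a patient's hazard by HR when that patient's expression
    is above the cohort median for the miRNA.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_patients
    mirnas = spec.mirna_ids()

    mutant = rng.random(n) < spec.mutant_fraction
    truncating = mutant & (rng.random(n) < spec.truncating_fraction)
    status = np.where(truncating, "truncating",
                      np.where(mutant, "missense", "wildtype"))

    node_pos = rng.random(n) < spec.node_positive_rate
    node_unknown = rng.random(n) < spec.node_unknown_rate
    node = np.where(node_unknown, "unknown",
                    np.where(node_pos, "N+", "N0"))

    base_means = rng.normal(6.0, 1.0, len(mirnas))
    log2x = rng.normal(0.0, spec.expression_sd, (n, len(mirnas)))
    log2x += base_means
    for k, mir in enumerate(mirnas):
        shift = spec.planted_mirna_shifts.get(mir, 0.0)
        log2x[status == "missense", k] += shift
        nshift = spec.node_effect_mirnas.get(mir, 0.0)
        log2x[(node == "N+"), k] += nshift

    lam0 = np.log(2) / spec.baseline_median_months
    hazard = np.full(n, lam0)
    for k, mir in enumerate(mirnas):
        hr = spec.survival_hazard_ratios.get(mir, 1.0)
        if hr != 1.0:
            high = log2x[:, k] >= np.median(log2x[:, k])
            hazard = np.where(high, hazard * hr, hazard)
    times = rng.exponential(1.0 / hazard)
    censored = rng.random(n) < spec.censoring_rate
    observed = np.where(censored, rng.uniform(0, times), times)

    df = pd.DataFrame({
        "patient_id": [f"P{i + 1:04d}" for i in range(n)],
        "p53_status": status,
        "node_status": node,
        "survival_months": np.round(observed, 3),
        "event": np.where(censored, 0, 1),
    })
    for k, mir in enumerate(mirnas):
        df[mir] = np.round(2.0 ** log2x[:, k], 4)
    return df
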