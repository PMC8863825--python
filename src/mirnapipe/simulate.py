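"""Synthetic-data generation for the miRNA pipeline.

Emulates the structure of a three-group circulating-miRNA cohort study
(healthy active / healthy sedentary / sedentary-at-risk) at every level the
downstream analysis touches:

* a precursor reference (hairpin FASTA + miRBase-dialect GFF3) with 5p/3p
  mature arms and optional mature sequences shared between precursors
  (multi-mappers);
* negative-binomial counts with group-specific log2 fold-changes for a
  designated differentially expressed subset, library-size variation, and a
  known ground truth;
* phenotype variables (metabolic-risk-like and fitness-like) linearly
  coupled to the group gradient and to the log-latent abundance of specific
  miRNAs, with declared association signs;
* per-sample gzipped FASTQ files (mature sequence + 3' adapter, truncated
  to the read length, with substitution errors on the insert).

All randomness flows from ``SimDesign.seed``; identical designs produce
byte-identical outputs.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .reference import MatureArm, Precursor, PrecursorSet

__all__ = [
    "SimDesign",
    "GroundTruth",
    "generate_reference",
    "simulate_counts",
    "write_fastq",
    "two_group_nb_counts",
    "COMPARISONS",
]

#: Pairwise comparisons run downstream, as (group B, group A) with the
#: fold-change reported for B relative to A.
COMPARISONS: tuple[tuple[str, str], ...] = (("HS", "HA"), ("SR", "HA"), ("SR", "HS"))

_DEFAULT_RISK_PHENOS = (
    "bmi",
    "fat_mass",
    "waist_circumference",
    "hs_crp",
    "systolic_bp_24h",
    "pwv",
    "ldl",
    "glucose",
)
_DEFAULT_FITNESS_PHENOS = ("vo2peak", "steps_per_day", "hdl", "avr")

# 3' adapter of a ligation-based small-RNA library prep.
_DEFAULT_ADAPTER = "AACTGTAGGCACCATCAAT"


@dataclass
class SimDesign:
    """Parameters of one synthetic cohort.

    The defaults describe the study conditions the pipeline targets: three
    groups of 38/36/84 participants, 300 mature miRNAs with a wide
    log-scale abundance range, a 13-miRNA "risk" block rising along the
    HA→HS→SR gradient and a 6-miRNA "health" block falling along it,
    metabolic-risk phenotypes positively associated with the risk block and
    negatively with the health block.
    """

    n_mirna: int = 300
    group_sizes: tuple[int, int, int] = (38, 36, 84)
    group_names: tuple[str, str, str] = ("HA", "HS", "SR")
    frac_de: float = 19 / 300
    logfc_magnitude: float = 2.0
    dispersion: float = 0.1
    lib_size_range: tuple[float, float] = (1.5e5, 2.5e5)
    baseline_logmean_range: tuple[float, float] = (0.0, 12.0)
    n_pheno: int = 12
    pheno_assoc: list[tuple[str, str, int]] | None = None
    pheno_alpha: float = 1.0
    pheno_beta: float = 0.5
    pheno_noise_sd: float = 1.0
    pheno_missing_frac: float = 0.0
    error_rate: float = 0.001
    adapter: str = _DEFAULT_ADAPTER
    read_length: int = 76
    shared_mature_frac: float = 0.0
    risk_block_size: int = 13
    health_block_size: int = 6
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_mirna < 2:
            raise ValueError("n_mirna must be >= 2")
        if len(self.group_sizes) != 3 or any(n < 2 for n in self.group_sizes):
            raise ValueError("three group sizes >= 2 are required")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError("frac_de must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0.0 <= self.error_rate < 0.25:
            raise ValueError("error_rate must lie in [0, 0.25)")
        if len(self.adapter) < 10:
            raise ValueError("adapter must be at least 10 nt")
        if not 0.0 <= self.shared_mature_frac <= 1.0:
            raise ValueError("shared_mature_frac must lie in [0, 1]")

    # -- derived layout -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return int(sum(self.group_sizes))

    def sample_ids(self) -> list[str]:
        ids = []
        for name, n in zip(self.group_names, self.group_sizes):
            ids.extend(f"{name}{k + 1:03d}" for k in range(n))
        return ids

    def sample_groups(self) -> pd.Series:
        labels = []
        for name, n in zip(self.group_names, self.group_sizes):
            labels.extend([name] * n)
        return pd.Series(labels, index=self.sample_ids(), name="group")

    def pheno_names(self) -> list[str]:
        names = list(_DEFAULT_RISK_PHENOS) + list(_DEFAULT_FITNESS_PHENOS)
        if self.n_pheno <= len(names):
            return names[: self.n_pheno]
        names += [f"param{k + 1}" for k in range(self.n_pheno - len(names))]
        return names

    def n_risk_phenos(self) -> int:
        return min(self.n_pheno, len(_DEFAULT_RISK_PHENOS))


@dataclass
class GroundTruth:
    """Injected truth of one simulation, judged against downstream output."""

    true_counts: pd.DataFrame  # mature miRNA x sample, integer
    de_flags: pd.DataFrame  # mature miRNA x comparison label, bool
    true_logfc: pd.DataFrame  # mature miRNA x comparison label, log2
    pheno_signs: list[tuple[str, str, int]]  # (mature id, phenotype, +-1)
    lib_sizes: pd.Series  # realized total counts per sample

    def __post_init__(self) -> None:
        if not (self.de_flags.values == (self.true_logfc.values != 0)).all():
            raise ValueError("de_flags must mark exactly the miRNAs with nonzero logFC")
        if list(self.true_counts.columns) != list(self.lib_sizes.index):
            raise ValueError("lib_sizes index must match sample columns")


# ---------------------------------------------------------------------------
# reference generation
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def generate_reference(design: SimDesign) -> PrecursorSet:
    """Build a random hairpin reference with annotated 5p/3p arms.

    Each precursor is a 5p mature (20-24 nt) + loop (10-20 nt) + 3p mature
    (20-24 nt); the 5p arm lies entirely in the first half of the hairpin
    and the 3p arm in the second half.  ``shared_mature_frac`` of mature
    sequences are copied into a second precursor to create multi-mapping
    loci.
    """
    rng = np.random.default_rng(design.seed)
    n_prec = (design.n_mirna + 1) // 2
    ref = PrecursorSet()
    parts: list[tuple[str, str, str]] = []
    for k in range(n_prec):
        five = _random_seq(rng, int(rng.integers(20, 25)))
        loop = _random_seq(rng, int(rng.integers(10, 21)))
        three = _random_seq(rng, int(rng.integers(20, 25)))
        # keep each arm within its half: pad the loop if an arm crosses L/2
        while len(five) > (len(five) + len(loop) + len(three)) / 2.0 or len(
            three
        ) > (len(five) + len(loop) + len(three)) / 2.0:
            loop += _random_seq(rng, 2)
        parts.append((five, loop, three))

    n_shared = int(round(design.shared_mature_frac * n_prec))
    # copy the 5p arm of precursor 2k into precursor 2k+1 (disjoint pairs)
    for k in range(n_shared):
        src, dst = 2 * k, 2 * k + 1
        if dst >= n_prec:
            break
        five, _, _ = parts[src]
        _, loop, three = parts[dst]
        parts[dst] = (five, loop, three)

    n_mature = 0
    for k, (five, loop, three) in enumerate(parts):
        pid = f"mir-sim-{k + 1:04d}"
        seq = five + loop + three
        ref.add_precursor(Precursor(pid, seq))
        ref.add_mature(MatureArm(f"miR-sim-{k + 1:04d}-5p", pid, 0, len(five), "5p"))
        n_mature += 1
        if n_mature >= design.n_mirna:
            break
        ref.add_mature(
            MatureArm(
                f"miR-sim-{k + 1:04d}-3p", pid, len(seq) - len(three), len(seq), "3p"
            )
        )
        n_mature += 1
        if n_mature >= design.n_mirna:
            break
    return ref


# ---------------------------------------------------------------------------
# count + phenotype simulation
# ---------------------------------------------------------------------------


def _nb_sample(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB draw with Var = mu + phi mu^2; phi = 0 degenerates to Poisson."""
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _group_offsets(design: SimDesign, mature_ids: list[str], rng: np.random.Generator):
    """Per-miRNA log2 expression offsets for the three groups.

    The first DE miRNAs form a graded "risk" block (0, +lfc/2, +lfc along
    the group order) and a graded "health" block (+lfc, +lfc/2, 0); any DE
    quota beyond the two blocks is assigned a single-group +-lfc shift.
    """
    n = len(mature_ids)
    n_de = int(round(design.frac_de * n))
    offsets = np.zeros((n, 3))
    lfc = design.logfc_magnitude
    risk = min(n_de, design.risk_block_size)
    health = min(n_de - risk, design.health_block_size)
    offsets[:risk] = [0.0, lfc / 2.0, lfc]
    offsets[risk : risk + health] = [lfc, lfc / 2.0, 0.0]
    for i in range(risk + health, n_de):
        g = int(rng.integers(0, 3))
        offsets[i, g] = lfc if rng.random() < 0.5 else -lfc
    return offsets, risk, health


def _default_pheno_assoc(
    design: SimDesign, mature_ids: list[str], n_risk: int, n_health: int
) -> list[tuple[str, str, int]]:
    names = design.pheno_names()
    n_metab = design.n_risk_phenos()
    if n_metab == 0:
        return []
    assoc = []
    for i in range(n_risk):
        assoc.append((mature_ids[i], names[i % n_metab], +1))
    for i in range(n_health):
        assoc.append((mature_ids[n_risk + i], names[i % n_metab], -1))
    return assoc


def simulate_counts(
    design: SimDesign, reference: PrecursorSet
) -> tuple[GroundTruth, pd.DataFrame]:
    """Draw NB counts and coupled phenotypes for one cohort.

    Counts: ``count_ij ~ NB(mean = s_j * p_i * 2**offset_i,g(j), phi)``
    where ``p_i`` are normalized baseline abundances and ``s_j`` the target
    library size.  Phenotypes: linear-Gaussian in the group gradient and in
    the z-scored log2 latent abundance of the associated miRNAs, with the
    declared signs.
    """
    rng = np.random.default_rng(design.seed + 1)
    mature_ids = reference.mature_ids()
    n = len(mature_ids)
    samples = design.sample_ids()
    groups = design.sample_groups()
    group_index = np.array(
        [design.group_names.index(g) for g in groups], dtype=int
    )

    lo, hi = design.baseline_logmean_range
    weights = 2.0 ** rng.uniform(lo, hi, size=n)
    p_base = weights / weights.sum()
    lib_targets = rng.uniform(*design.lib_size_range, size=len(samples))

    offsets, n_risk, n_health = _group_offsets(design, mature_ids, rng)
    log2_mean = (
        np.log2(p_base)[:, None]
        + np.log2(lib_targets)[None, :]
        + offsets[:, group_index]
    )
    mean = 2.0**log2_mean
    counts = _nb_sample(rng, mean, design.dispersion)
    true_counts = pd.DataFrame(counts, index=mature_ids, columns=samples)

    labels = [f"{b}_vs_{a}" for b, a in COMPARISONS]
    logfc = np.zeros((n, len(COMPARISONS)))
    for c, (b, a) in enumerate(COMPARISONS):
        gb, ga = design.group_names.index(b), design.group_names.index(a)
        logfc[:, c] = offsets[:, gb] - offsets[:, ga]
    true_logfc = pd.DataFrame(logfc, index=mature_ids, columns=labels)
    de_flags = true_logfc != 0.0

    # phenotypes: group gradient (risk params rise, fitness params fall)
    # plus z-scored log2 latent abundance of the associated miRNAs
    assoc = design.pheno_assoc
    if assoc is None:
        assoc = _default_pheno_assoc(design, mature_ids, n_risk, n_health)
    names = design.pheno_names()
    n_metab = design.n_risk_phenos()
    gradient = group_index / max(len(design.group_names) - 1, 1)
    pheno = np.zeros((len(samples), len(names)))
    mature_pos = {m: i for i, m in enumerate(mature_ids)}
    for p, name in enumerate(names):
        alpha = design.pheno_alpha if p < n_metab else -design.pheno_alpha
        x = alpha * gradient + design.pheno_noise_sd * rng.standard_normal(
            len(samples)
        )
        for mid, pname, sign in assoc:
            if pname != name:
                continue
            lat = log2_mean[mature_pos[mid]]
            sd = lat.std()
            z = (lat - lat.mean()) / sd if sd > 0 else np.zeros_like(lat)
            x = x + design.pheno_beta * sign * z
        pheno[:, p] = x
    pheno_df = pd.DataFrame(pheno, index=samples, columns=names)
    pheno_df.insert(0, "group", groups.values)
    if design.pheno_missing_frac > 0:
        mask = rng.random(pheno.shape) < design.pheno_missing_frac
        vals = pheno_df[names].to_numpy()
        vals[mask] = np.nan
        pheno_df[names] = vals

    truth = GroundTruth(
        true_counts=true_counts,
        de_flags=de_flags,
        true_logfc=true_logfc,
        pheno_signs=list(assoc),
        lib_sizes=true_counts.sum(axis=0),
    )
    return truth, pheno_df


def two_group_nb_counts(
    n_genes: int,
    n_per_group: tuple[int, int],
    frac_de: float = 0.0,
    logfc_magnitude: float = 2.0,
    dispersion: float = 0.1,
    baseline_logmean_range: tuple[float, float] = (2.0, 10.0),
    lib_size_range: tuple[float, float] = (0.8e6, 1.2e6),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, np.ndarray, np.ndarray]:
    """Two-group NB benchmark matrix for the differential-expression tests.

    Returns (counts, group labels, DE flags, true log2 fold-changes); DE
    genes shift group B by ``+-logfc_magnitude`` with alternating sign.
    """
    rng = np.random.default_rng(seed)
    nA, nB = n_per_group
    lo, hi = baseline_logmean_range
    weights = 2.0 ** rng.uniform(lo, hi, size=n_genes)
    p_base = weights / weights.sum()
    libs = rng.uniform(*lib_size_range, size=nA + nB)
    n_de = int(round(frac_de * n_genes))
    lfc = np.zeros(n_genes)
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
    lfc[de_idx] = signs * logfc_magnitude
    shift = np.zeros((n_genes, nA + nB))
    shift[:, nA:] = lfc[:, None]
    mean = p_base[:, None] * libs[None, :] * 2.0**shift
    counts = _nb_sample(rng, mean, dispersion)
    genes = [f"g{i + 1}" for i in range(n_genes)]
    samples = [f"A{j + 1}" for j in range(nA)] + [f"B{j + 1}" for j in range(nB)]
    groups = pd.Series(["A"] * nA + ["B"] * nB, index=samples, name="group")
    return (
        pd.DataFrame(counts, index=genes, columns=samples),
        groups,
        lfc != 0,
        lfc,
    )


# ---------------------------------------------------------------------------
# read-level emulation
# ---------------------------------------------------------------------------


def _mutate(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    hits = np.nonzero(rng.random(len(seq)) < error_rate)[0]
    if hits.size == 0:
        return seq
    chars = list(seq)
    for i in hits:
        alternatives = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alternatives[int(rng.integers(0, 3))]
    return "".join(chars)


def write_fastq(
    truth: GroundTruth,
    reference: PrecursorSet,
    design: SimDesign,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write one gzipped FASTQ per sample from the true counts.

    Each count unit becomes one read: mature sequence + 3' adapter,
    truncated to the read length, substitution errors applied to the
    insert at ``error_rate``.  Read names carry only the sample id and a
    serial number; quality is a constant 'I' line.  Output is byte-stable
    for a fixed design (gzip mtime pinned to 0).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(design.seed + 2)
    mature_seqs = {m: reference.mature_sequence(m) for m in truth.true_counts.index}
    paths: dict[str, Path] = {}
    for sample in truth.true_counts.columns:
        counts = truth.true_counts[sample]
        order = np.repeat(
            np.arange(len(counts)), counts.to_numpy().astype(np.int64)
        )
        rng.shuffle(order)
        path = out_dir / f"{sample}.fastq.gz"
        with open(path, "wb") as raw:
            with gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0) as fh:
                chunks: list[str] = []
                for serial, idx in enumerate(order, start=1):
                    insert = mature_seqs[counts.index[idx]]
                    if design.error_rate > 0:
                        insert = _mutate(insert, rng, design.error_rate)
                    read = (insert + design.adapter)[: design.read_length]
                    chunks.append(
                        f"@{sample}_{serial}\n{read}\n+\n{'I' * len(read)}\n"
                    )
                    if len(chunks) >= 50_000:
                        fh.write("".join(chunks).encode())
                        chunks = []
                fh.write("".join(chunks).encode())
        paths[sample] = path
    return paths
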