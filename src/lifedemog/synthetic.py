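"""Synthetic data with the statistical structure the pipeline assumes.

Three generators live here:

* **Cohorts** — individual life histories censused every 12 h, with a
  per-interval death probability (piecewise-constant or Gompertz) and
  Poisson offspring at an age-dependent rate, emulating a monogonont
  rotifer life-table experiment (one neonate per well, followed until
  death, at least 24 females per species x temperature).
* **Hit tables** — BLAST tabular (outfmt 6) alignment results of
  assembled contigs against a target genome, competitor (algal)
  databases and an rRNA database, with known ground-truth classes, for
  testing the bit-score-gain decontamination rule.
* **Count matrices** — negative-binomial gene x sample counts with a
  planted subset of genes violating the low-count filter criteria.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .life_table import CohortTable, IndividualRecord

__all__ = [
    "CohortParams",
    "DesignSpec",
    "simulate_cohort",
    "analytic_schedule",
    "simulate_design",
    "tolerant_preset",
    "sensitive_preset",
    "two_species_demo",
    "simulate_hit_table",
    "simulate_count_matrix",
    "write_hit_table",
    "write_count_matrix",
]


class ParameterError(ValueError):
    """Invalid generator parameters."""


@dataclass(frozen=True)
class CohortParams:
    """Generating process of one (species, temperature) cohort.

    The hazard is given either as explicit per-interval death
    probabilities ``q`` (each in [0, 1], recycled to ``max_intervals`` by
    repeating the last value) or as a Gompertz pair ``(a, b)`` with
    hazard rate ``h(t) = a * exp(b * t)`` per day, converted to interval
    death probabilities through the cumulative hazard.  Fecundity ``f``
    is the expected offspring per interval (Poisson), recycled the same
    way.
    """

    species: str
    temperature: float
    n_individuals: int = 24
    census_interval: float = 0.5
    q: tuple[float, ...] | None = None
    gompertz: tuple[float, float] | None = None
    fecundity: tuple[float, ...] = (0.0,)
    max_intervals: int = 200

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ParameterError("n_individuals must be >= 1")
        if self.census_interval <= 0:
            raise ParameterError("census_interval must be positive")
        if self.max_intervals < 1:
            raise ParameterError("max_intervals must be >= 1")
        if (self.q is None) == (self.gompertz is None):
            raise ParameterError("specify exactly one of q or gompertz")
        if self.q is not None:
            q = tuple(float(v) for v in self.q)
            if not q or any(v < 0 or v > 1 for v in q):
                raise ParameterError("q values must lie in [0, 1]")
            object.__setattr__(self, "q", q)
        else:
            a, b = self.gompertz
            if a <= 0 or b < 0:
                raise ParameterError("Gompertz requires a > 0 and b >= 0")
        f = tuple(float(v) for v in self.fecundity)
        if not f or any(v < 0 for v in f):
            raise ParameterError("fecundity values must be >= 0")
        object.__setattr__(self, "fecundity", f)

    def interval_death_probs(self) -> np.ndarray:
        """Per-interval death probabilities q_j, j = 1..max_intervals."""
        if self.q is not None:
            q = np.asarray(self.q, dtype=float)
            if len(q) < self.max_intervals:
                q = np.concatenate(
                    [q, np.full(self.max_intervals - len(q), q[-1])]
                )
            return q[: self.max_intervals]
        a, b = self.gompertz
        t = np.arange(self.max_intervals + 1, dtype=float) * self.census_interval
        if b == 0:
            cumhaz = a * t
        else:
            cumhaz = (a / b) * np.expm1(b * t)
        return 1.0 - np.exp(-np.diff(cumhaz))

    def interval_fecundity(self) -> np.ndarray:
        """Expected offspring per interval f_j, j = 1..max_intervals."""
        f = np.asarray(self.fecundity, dtype=float)
        if len(f) < self.max_intervals:
            f = np.concatenate([f, np.full(self.max_intervals - len(f), f[-1])])
        return f[: self.max_intervals]


@dataclass(frozen=True)
class DesignSpec:
    """A multi-treatment experimental design with one global seed."""

    treatments: tuple[CohortParams, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.treatments:
            raise ParameterError("design must contain at least one treatment")
        keys = [(p.species, p.temperature) for p in self.treatments]
        if len(set(keys)) != len(keys):
            raise ParameterError("duplicate (species, temperature) treatment")


def _subseed(global_seed: int, species: str, temperature: float) -> int:
    """Deterministic per-treatment sub-seed, independent of treatment order."""
    key = f"{global_seed}|{species}|{temperature:.6g}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


def simulate_cohort(params: CohortParams, seed: int) -> list[IndividualRecord]:
    """Simulate one cohort of individual life histories.

    Each individual is followed interval by interval: offspring are drawn
    Poisson(f_j) for every interval she starts alive (a female dying
    within an interval still yields the neonates observed at its closing
    census), then death occurs with probability q_j.  Individuals alive
    after ``max_intervals`` are marked censored at the cap.
    """
    rng = np.random.default_rng(seed)
    q = params.interval_death_probs()
    f = params.interval_fecundity()
    records = []
    for i in range(params.n_individuals):
        offspring: list[int] = []
        death_interval = params.max_intervals
        censored = True
        for j in range(params.max_intervals):
            offspring.append(int(rng.poisson(f[j])) if f[j] > 0 else 0)
            if rng.random() < q[j]:
                death_interval = j + 1
                censored = False
                break
        records.append(
            IndividualRecord(
                individual_id=f"{params.species}_{params.temperature:g}_{i + 1:03d}",
                species=params.species,
                temperature=params.temperature,
                death_interval=death_interval,
                offspring=tuple(offspring),
                censored=censored,
                census_interval=params.census_interval,
            )
        )
    return records


def analytic_schedule(params: CohortParams) -> CohortTable:
    """Expected (x, lx, mx) schedule of the generating process.

    ``lx[j] = prod_{i<j} (1 - q_i)`` and ``mx[j] = f_j``; this is the
    exact large-n limit of a simulated cohort's life table and serves as
    the ground truth in parameter-recovery tests.
    """
    q = params.interval_death_probs()
    f = params.interval_fecundity()
    lx = np.concatenate([[1.0], np.cumprod(1.0 - q)[:-1]])
    x = np.arange(params.max_intervals, dtype=float) * params.census_interval
    return CohortTable(
        x=x, lx=lx, mx=f, n0=params.n_individuals,
        census_interval=params.census_interval,
    )


def simulate_design(spec: DesignSpec) -> list[IndividualRecord]:
    """Simulate every treatment of a design with order-independent sub-seeds."""
    records: list[IndividualRecord] = []
    for params in spec.treatments:
        sub = _subseed(spec.seed, params.species, params.temperature)
        records.extend(simulate_cohort(params, sub))
    return records


# ---------------------------------------------------------------------------
# presets emulating the two-species thermal-tolerance contrast

def tolerant_preset(temperature: float, n_individuals: int = 24) -> CohortParams:
    """Heat-tolerant species: hazard rises with temperature, fecundity
    holds up until the warmest assay."""
    base_a = 0.02 * np.exp(0.12 * (temperature - 20.0))
    fec_peak = 2.0 if temperature < 32.0 else 1.0
    fecundity = _fecundity_profile(peak=fec_peak, onset=2, span=14)
    return CohortParams(
        species="tolerant",
        temperature=temperature,
        n_individuals=n_individuals,
        gompertz=(base_a, 0.35),
        fecundity=fecundity,
    )


def sensitive_preset(temperature: float, n_individuals: int = 24) -> CohortParams:
    """Heat-sensitive species: lower thermal optimum, hazard climbs faster."""
    base_a = 0.015 * np.exp(0.22 * (temperature - 20.0))
    fec_peak = 2.0 if temperature < 26.0 else 0.8
    fecundity = _fecundity_profile(peak=fec_peak, onset=3, span=16)
    return CohortParams(
        species="sensitive",
        temperature=temperature,
        n_individuals=n_individuals,
        gompertz=(base_a, 0.30),
        fecundity=fecundity,
    )


def _fecundity_profile(peak: float, onset: int, span: int) -> tuple[float, ...]:
    """Humped age-fecundity curve: zero before maturity, peak, slow decline."""
    f = np.zeros(onset + span + 1)
    ages = np.arange(span)
    f[onset:onset + span] = peak * np.exp(-0.5 * ((ages - span / 3) / (span / 3)) ** 2)
    return tuple(f)


def two_species_demo(seed: int = 0, n_individuals: int = 24) -> DesignSpec:
    """The 2-species x multi-temperature demo design used by the CLI."""
    treatments = tuple(
        [tolerant_preset(t, n_individuals) for t in (20.0, 23.0, 26.0, 32.0)]
        + [sensitive_preset(t, n_individuals) for t in (20.0, 23.0, 26.0)]
    )
    return DesignSpec(treatments=treatments, seed=seed)


# ---------------------------------------------------------------------------
# hit tables for the decontamination filter

_HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

_CLASSES = ("target", "contaminant", "rrna", "nohit", "ambiguous")


def simulate_hit_table(
    n_contigs: int,
    class_mix: dict[str, float],
    seed: int,
    *,
    gain_threshold: float = 100.0,
    target_label: str = "rotifer_genome",
    contaminant_labels: Sequence[str] = ("algae_mono", "algae_chlamy", "algae_crypto"),
    rrna_label: str = "rrna_18s28s",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate an outfmt-6 hit table with known contig classes.

    ``class_mix`` assigns proportions to the classes ``target``,
    ``contaminant``, ``rrna``, ``nohit`` and ``ambiguous`` (must sum to
    1).  Target contigs receive a best-target bit-score exceeding the
    best competitor score by a margin drawn strictly above
    ``gain_threshold``; ambiguous contigs by a margin in
    ``(0, gain_threshold]``; contaminant contigs have their best hit in a
    competitor database.  rRNA contigs hit the rRNA database at a very
    small e-value.

    Returns
    -------
    hits, labels, truth : DataFrame
        The hit table (outfmt-6 columns), the sseqid -> database label
        sidecar, and the per-contig ground truth.
    """
    if n_contigs < 0:
        raise ParameterError("n_contigs must be >= 0")
    unknown = set(class_mix) - set(_CLASSES)
    if unknown:
        raise ParameterError(f"unknown classes in mix: {sorted(unknown)}")
    probs = np.array([class_mix.get(c, 0.0) for c in _CLASSES], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ParameterError(f"class mix must sum to 1, got {probs.sum()}")

    rng = np.random.default_rng(seed)
    classes = rng.choice(len(_CLASSES), size=n_contigs, p=probs)

    rows = []
    labels: dict[str, str] = {}
    truth_rows = []

    def add_hit(contig, subject, label, bitscore, evalue):
        labels[subject] = label
        rows.append(
            (
                contig, subject,
                round(float(rng.uniform(80, 100)), 2),
                int(rng.integers(100, 1500)),
                int(rng.integers(0, 30)), int(rng.integers(0, 5)),
                1, 100, 1, 100,
                evalue, round(float(bitscore), 1),
            )
        )

    for i, cls_idx in enumerate(classes):
        contig = f"contig_{i + 1:05d}"
        cls = _CLASSES[cls_idx]
        truth_rows.append((contig, "unassigned" if cls == "nohit" else cls))
        if cls == "nohit":
            continue
        if cls == "rrna":
            add_hit(contig, f"{rrna_label}_seq1", rrna_label,
                    rng.uniform(500, 2000), 1e-30)
            continue
        base = float(rng.uniform(200, 800))
        contam_db = str(rng.choice(list(contaminant_labels)))
        if cls == "target":
            margin = gain_threshold + float(rng.uniform(1.0, 200.0))
            add_hit(contig, f"{target_label}_scf{i}", target_label, base + margin, 1e-40)
            add_hit(contig, f"{contam_db}_s{i}", contam_db, base, 1e-20)
        elif cls == "ambiguous":
            margin = float(rng.uniform(0.5, gain_threshold))
            add_hit(contig, f"{target_label}_scf{i}", target_label, base + margin, 1e-40)
            add_hit(contig, f"{contam_db}_s{i}", contam_db, base, 1e-20)
        else:  # contaminant: best hit in a competitor database
            margin = float(rng.uniform(10.0, 300.0))
            add_hit(contig, f"{contam_db}_s{i}", contam_db, base + margin, 1e-40)
            if rng.random() < 0.7:
                add_hit(contig, f"{target_label}_scf{i}", target_label, base, 1e-10)

    hits = pd.DataFrame(rows, columns=_HIT_COLUMNS)
    label_frame = pd.DataFrame(
        sorted(labels.items()), columns=["sseqid", "database"]
    )
    truth = pd.DataFrame(truth_rows, columns=["qseqid", "true_class"])
    return hits, label_frame, truth


def write_hit_table(hits: pd.DataFrame, labels: pd.DataFrame, truth: pd.DataFrame,
                    prefix) -> None:
    """Write hits/labels/truth as TSV next to each other (BLAST outfmt-6 style)."""
    hits.to_csv(f"{prefix}.hits.tsv", sep="\t", index=False, header=False)
    labels.to_csv(f"{prefix}.labels.tsv", sep="\t", index=False)
    truth.to_csv(f"{prefix}.truth.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# count matrices for the low-count gene filter

def simulate_count_matrix(
    n_genes: int,
    n_samples: int,
    seed: int,
    low_count_fraction: float = 0.2,
    *,
    min_count: int = 10,
    min_replicates: int = 2,
    mean_expression: float = 200.0,
    dispersion: float = 0.3,
) -> tuple[pd.DataFrame, pd.Series]:
    """Negative-binomial counts with a planted low-count gene subset.

    A fraction ``low_count_fraction`` of genes is constructed to violate
    the retention rule (total count >= ``min_count`` and nonzero in >=
    ``min_replicates`` samples): half of them by total count, half by
    being expressed in a single sample.  Returns the gene x sample
    matrix and a boolean Series flagging the genes a correct filter must
    KEEP.
    """
    if n_genes < 1 or n_samples < 1:
        raise ParameterError("dimensions must be >= 1")
    if not 0.0 <= low_count_fraction <= 1.0:
        raise ParameterError("low_count_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)

    n_low = int(round(low_count_fraction * n_genes))
    genes = [f"gene_{i + 1:05d}" for i in range(n_genes)]
    samples = [f"sample_{j + 1:02d}" for j in range(n_samples)]

    # NB as Gamma-Poisson
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean_expression / shape, size=(n_genes, n_samples))
    counts = rng.poisson(lam).astype(np.int64)

    low_idx = rng.permutation(n_genes)[:n_low]
    is_kept = np.ones(n_genes, dtype=bool)
    is_kept[low_idx] = False
    # guarantee the "keep" genes actually satisfy the retention rule
    keep_idx = np.flatnonzero(is_kept)
    for gi in keep_idx:
        row = counts[gi]
        deficit = min_count - int(row.sum())
        if deficit > 0:
            row[0] += deficit
        for k in range(min(min_replicates, n_samples)):
            row[k] = max(row[k], 1)
    for rank, gi in enumerate(low_idx):
        if rank % 2 == 0 or n_samples < 2:
            # violate the total-count criterion
            row = np.zeros(n_samples, dtype=np.int64)
            total = int(rng.integers(0, min_count))  # < min_count
            if n_samples >= 2 and total >= 2:
                row[0] = total - 1
                row[1] = 1
            else:
                row[0] = total
            counts[gi] = row
        else:
            # expressed in a single sample only, but high there
            row = np.zeros(n_samples, dtype=np.int64)
            row[int(rng.integers(0, n_samples))] = int(rng.integers(50, 500))
            counts[gi] = row
        is_kept[gi] = False

    matrix = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"),
                          columns=samples)
    truth = pd.Series(is_kept, index=matrix.index, name="kept")
    return matrix, truth


def write_count_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")
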