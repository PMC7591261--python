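"""Synthetic count matrices with planted phase-specific genes.

The generator emulates the synchronized design the pipeline analyses: five
cell-cycle phases x two biological replicates of negative-binomial counts.
Gene baselines are log-normal in CPM units, a chosen fraction of genes gets
a single multiplicative peak in one phase (step profile), library sizes vary
log-normally, and every gene carries a biotype label. The planted truth is
returned alongside so recovery can be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import BIOTYPES, PHASES, CountMatrix


def _sanitize(phase: str) -> str:
    return phase.replace("/", "")


@dataclass
class SimConfig:
    """Study conditions for the count simulator.

    Defaults give the headline recovery scenario: 5000 genes, 4% planted
    phase-specific at 4-fold, dispersion 0.05, library sizes around 2e6
    reads with 20% CV, two replicates per phase.
    """

    n_genes: int = 5000
    phases: tuple[str, ...] = PHASES
    replicates_per_phase: int = 2
    frac_phase_specific: float = 0.04
    peak_fold_change: float = 4.0
    dispersion: float = 0.05
    #: (mu, sigma) of per-gene log2 baseline mean, in CPM units. The default
    #: models a panel of moderately expressed genes (median 32 CPM, central
    #: 95% roughly 4-256 CPM) so that planted effects are above the
    #: detection floor of a two-replicate design at the default depth.
    baseline_mean_log2: tuple[float, float] = (5.0, 1.5)
    library_size_mean: float = 2e6
    library_size_cv: float = 0.2
    library_sizes: tuple[int, ...] | None = None
    biotype_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "protein_coding": 0.65,
            "lncRNA": 0.33,
            "pseudogene": 0.015,
            "other": 0.005,
        }
    )
    seed: int = 20431

    def __post_init__(self) -> None:
        if not 0 <= self.frac_phase_specific <= 1:
            raise ValidationError("frac_phase_specific must be in [0, 1]")
        if self.peak_fold_change <= 1:
            raise ValidationError("peak_fold_change must be > 1")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        if set(self.biotype_proportions) != set(BIOTYPES):
            raise ValidationError(f"biotype_proportions must cover {BIOTYPES}")
        total = sum(self.biotype_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"biotype proportions sum to {total}, not 1")


def simulate_counts(config: SimConfig | None = None) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw a (CountMatrix, truth table) pair under the configured conditions.

    The mean of gene g in a sample of phase q with library size L is
    ``baseline_g * fc_g(q) * L / 1e6`` where fc_g(q) is the planted fold
    change when q is the gene's peak phase and 1 otherwise. Counts are NB
    with common dispersion (Poisson when dispersion is 0). The number of
    planted genes is exact and they are allocated round-robin over phases.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    phases = list(config.phases)
    reps = config.replicates_per_phase

    gene_ids = [f"G{i+1:05d}" for i in range(n)]
    sample_ids, sample_phase, sample_rep = [], [], []
    for q in phases:
        for r in range(1, reps + 1):
            sample_ids.append(f"{_sanitize(q)}_{r}")
            sample_phase.append(q)
            sample_rep.append(r)
    n_samples = len(sample_ids)

    mu, sigma = config.baseline_mean_log2
    baseline = 2.0 ** rng.normal(mu, sigma, size=n)

    n_spec = int(round(config.frac_phase_specific * n))
    spec_idx = np.sort(rng.choice(n, size=n_spec, replace=False))
    peak = np.array([None] * n, dtype=object)
    for j, g in enumerate(spec_idx):
        peak[g] = phases[j % len(phases)]

    if config.library_sizes is not None:
        lib = np.asarray(config.library_sizes, dtype=float)
        if len(lib) != n_samples:
            raise ValidationError("library_sizes length does not match design")
    else:
        cv = config.library_size_cv
        s2 = np.log(1 + cv**2)
        lib = rng.lognormal(np.log(config.library_size_mean) - s2 / 2, np.sqrt(s2), n_samples)
    lib = np.maximum(np.rint(lib), 1).astype(np.int64)

    fc = np.ones((n, n_samples))
    for j, q in enumerate(sample_phase):
        fc[:, j] = np.where(peak == q, config.peak_fold_change, 1.0)
    mean = baseline[:, None] * fc * (lib[None, :] / 1e6)

    phi = config.dispersion
    if phi == 0:
        counts = rng.poisson(mean)
    else:
        r = 1.0 / phi
        counts = rng.negative_binomial(r, r / (r + mean))

    biotypes = rng.choice(
        list(config.biotype_proportions),
        size=n,
        p=list(config.biotype_proportions.values()),
    )

    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)
    samples = pd.DataFrame(
        {"sample_id": sample_ids, "phase": sample_phase, "replicate": sample_rep}
    )
    cm = CountMatrix(counts_df, samples, pd.Series(lib, index=sample_ids))
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "class": np.where(peak == None, "null", "phase_specific"),  # noqa: E711
            "peak_phase": [p if p is not None else "none" for p in peak],
            "planted_fc": np.where(peak == None, 1.0, config.peak_fold_change),  # noqa: E711
            "biotype": biotypes,
            "baseline_mean": baseline,
        },
        index=gene_ids,
    )
    return cm, truth


def simulate_survival(
    n_per_group: int = 100,
    hazard_low: float = 0.1,
    hazard_ratio: float = 3.0,
    censor_rate: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential survival fixture for the median-split comparison.

    The high-expression group has hazard ``hazard_low * hazard_ratio``
    (higher expression, worse survival). Censoring times are exponential
    with rate chosen so each group's expected censored fraction equals
    ``censor_rate``. Expression is drawn so the pooled median separates the
    groups exactly.
    """
    if hazard_low <= 0 or hazard_ratio <= 0:
        raise ValidationError("hazards must be > 0")
    if not 0 <= censor_rate < 1:
        raise ValidationError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    for name, hazard, lo, hi in (
        ("low", hazard_low, 0.0, 1.0),
        ("high", hazard_low * hazard_ratio, 1.0, 2.0),
    ):
        t_event = rng.exponential(1 / hazard, n_per_group)
        if censor_rate > 0:
            rate_c = hazard * censor_rate / (1 - censor_rate)
            t_cens = rng.exponential(1 / rate_c, n_per_group)
        else:
            t_cens = np.full(n_per_group, np.inf)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        expr = rng.uniform(lo, hi, n_per_group)
        for i in range(n_per_group):
            rows.append(
                {
                    "sample_id": f"{name}_{i+1:04d}",
                    "time": time[i],
                    "event": event[i],
                    "expression": expr[i],
                    "true_group": name,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# deterministic desk-scale fixture

_FIXTURE_LIB = 40_000_000  # per-sample library size; CPM = count / 40


def fixture_counts() -> tuple[CountMatrix, pd.DataFrame]:
    """Deterministic 30-gene x 10-sample fixture with known outcomes.

    Contains one hand-built phase-specific gene per phase (PEAK_*), two
    tie-case genes whose maximum is duplicated in two adjacent phases
    (TIE_*), an all-zero gene, one gene sitting exactly on the CPM filter
    boundary in two samples (kept) and one exceeding it in a single sample
    only (dropped), plus stably expressed null genes.
    """
    phases = list(PHASES)
    sample_ids = [f"{_sanitize(q)}_{r}" for q in phases for r in (1, 2)]
    phase_of = {s: q for q, s in zip([q for q in phases for _ in (1, 2)], sample_ids)}

    def per_phase(values: dict[str, int], default: int) -> list[int]:
        return [values.get(phase_of[s], default) for s in sample_ids]

    rows: dict[str, list[int]] = {}
    for q in phases:
        rows[f"PEAK_{_sanitize(q)}"] = per_phase({q: 400}, 40)
    rows["TIE_S_G2"] = per_phase({"S": 200, "G2": 200}, 40)
    rows["TIE_M_G1"] = per_phase({"M": 200, "G1": 200}, 40)
    rows["ALLZERO"] = [0] * 10
    # CPM = 3/40e6*1e6 = 0.075 in exactly the two G1 samples, below elsewhere
    rows["BOUND_KEEP"] = per_phase({"G1": 3}, 2)
    # above threshold in a single sample only -> filtered out
    rows["BOUND_DROP"] = [3 if s == "S_1" else 0 for s in sample_ids]

    null_bases = [20, 30, 45, 60, 80, 100, 130, 160, 200, 250,
                  300, 400, 500, 650, 800, 1000, 1300, 1600, 2000, 2500]
    jitter = [1.00, 1.02, 0.98, 1.01, 0.99, 1.03, 0.97, 1.00, 1.02, 0.98]
    for i, base in enumerate(null_bases):
        # rotate the jitter pattern so no two nulls co-vary identically
        rows[f"NULL_{i+1:02d}"] = [
            int(round(base * jitter[(j + i) % 10])) for j in range(10)
        ]

    counts = pd.DataFrame(rows).T
    counts.columns = sample_ids
    counts.index.name = "gene_id"
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "phase": [phase_of[s] for s in sample_ids],
            "replicate": [int(s.rsplit("_", 1)[1]) for s in sample_ids],
        }
    )
    lib = pd.Series(_FIXTURE_LIB, index=sample_ids)
    cm = CountMatrix(counts, samples, lib)

    def truth_row(g: str) -> dict:
        if g.startswith("PEAK_"):
            tag = g.split("_", 1)[1]
            phase = {_sanitize(q): q for q in phases}[tag]
            return {"class": "phase_specific", "peak_phase": phase}
        return {"class": "null", "peak_phase": "none"}

    truth = pd.DataFrame(
        [{"gene_id": g, **truth_row(g)} for g in counts.index],
        index=counts.index,
    )
    return cm, truth
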