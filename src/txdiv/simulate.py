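"""Synthetic bulk-transcriptome cohorts with controlled diversity mechanisms.

The generator produces gene x sample count matrices with the statistical
structure the diversity analyses assume: a heavy-tailed log-normal
baseline of expected relative abundances, negative-binomial sequencing
noise, and two disease mechanisms that perturb opposite ends of the
rank-abundance curve:

* ``low_loss`` — genes in the low-abundance tail (below rank quantile
  ``q_low``) are silenced with a severity-scaled probability or attenuated
  by ``delta**severity``; richness and evenness fall.
* ``high_gain`` — genes in the high-abundance head (above ``q_high``) are
  amplified by ``gamma**severity``; the expressed-gene set is preserved
  while dominance rises.

Severity follows a per-group ladder (control = 0, so the control arm is
exactly the unperturbed baseline). A separate mixture mode draws
per-sample Dirichlet cell-type proportions over user signatures, for
deconvolution ground-truth recovery tests. All randomness flows from a
single integer seed; outputs are byte-identical across reruns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GroupDesign, MarkerReference, tpm_from_counts

MECHANISMS = ("none", "low_loss", "high_gain", "mixed")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Defaults emulate a three-group bulk liver RNA-seq study: 10/11/18
    samples, 10,000 genes, log-normal abundance with sdlog 2 (a few
    dominant transcripts over a long low-abundance tail), negative-
    binomial noise with size 10, 5e6 reads per sample, and a
    severity ladder applying the selected mechanism progressively.
    """

    n_genes: int = 10_000
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"HC": 10, "ASH": 11, "AH": 18})
    meanlog: float = 0.0
    sdlog: float = 2.0
    mechanism: str = "low_loss"
    q_low: float = 0.9            # rank quantile below which low_loss acts
    silencing_prob: float = 0.15  # per-unit-severity silencing probability
    attenuation: float = 0.4      # delta in (0,1): survivor multiplier base
    q_high: float = 0.9           # rank quantile above which high_gain acts
    amplification: float = 1.5    # gamma > 1: amplification base
    severity: dict[str, float] = field(
        default_factory=lambda: {"HC": 0.0, "ASH": 1.0, "AH": 2.0})
    depth: float = 5_000_000.0
    dispersion: float = 10.0      # NB size k: var = mu + mu^2/k; inf = Poisson
    gene_length: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}; "
                             f"choose from {MECHANISMS}")
        if not (0 < self.q_low < 1 and 0 < self.q_high < 1):
            raise ValueError("rank quantiles must lie in (0, 1)")
        if not 0 < self.attenuation < 1:
            raise ValueError("attenuation delta must lie in (0, 1)")
        if not self.amplification > 1:
            raise ValueError("amplification gamma must exceed 1")
        if not 0 <= self.silencing_prob <= 1:
            raise ValueError("silencing probability must lie in [0, 1]")
        if self.depth <= 0:
            raise ValueError("sequencing depth must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def simulate_baseline(config: SimulationConfig,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw per-gene expected relative abundances (log-normal, sum 1)."""
    rng = rng or np.random.default_rng(config.seed)
    if config.sdlog == 0:
        w = np.full(config.n_genes, np.exp(config.meanlog))
    else:
        w = rng.lognormal(config.meanlog, config.sdlog, config.n_genes)
    return w / w.sum()


def apply_mechanism(baseline: np.ndarray, config: SimulationConfig,
                    severity: float,
                    rng: np.random.Generator | None = None):
    """Perturb expected abundances by the configured mechanism.

    Returns ``(perturbed, affected)`` where ``affected`` is the boolean
    mask of genes the mechanism touched. Severity 0 is the identity.
    """
    rng = rng or np.random.default_rng(config.seed)
    w = np.asarray(baseline, dtype=float).copy()
    affected = np.zeros(len(w), dtype=bool)
    if severity == 0 or config.mechanism == "none":
        return w, affected

    # rank quantiles over ascending abundance: rank 0 = least abundant
    order = np.argsort(np.argsort(w, kind="stable"))
    quantile = (order + 0.5) / len(w)

    if config.mechanism in ("low_loss", "mixed"):
        low = quantile < config.q_low
        p_silence = min(config.silencing_prob * severity, 1.0)
        silenced = low & (rng.random(len(w)) < p_silence)
        attenuated = low & ~silenced
        w[silenced] = 0.0
        w[attenuated] *= config.attenuation ** severity
        affected |= low
    if config.mechanism in ("high_gain", "mixed"):
        high = quantile > config.q_high
        w[high] *= config.amplification ** severity
        affected |= high

    total = w.sum()
    if total <= 0:
        raise ValueError("mechanism silenced every gene; lower q_low or pi")
    return w / total, affected


def simulate_counts(expected_abundance, depth: float, dispersion: float,
                    n_samples: int, rng_or_seed) -> np.ndarray:
    """Draw a gene x sample integer count matrix with NB noise.

    Counts are gamma-Poisson: mean = depth * abundance, variance =
    mu + mu^2/dispersion. ``dispersion=np.inf`` gives pure Poisson.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = (rng_or_seed if isinstance(rng_or_seed, np.random.Generator)
           else np.random.default_rng(rng_or_seed))
    w = np.asarray(expected_abundance, dtype=float)
    if abs(w.sum() - 1.0) > 1e-6:
        raise ValueError("expected abundances must sum to 1")
    mu = np.tile((depth * w)[:, None], (1, n_samples))
    if np.isinf(dispersion):
        lam = mu
    else:
        lam = rng.gamma(shape=dispersion, scale=mu / dispersion)
    return rng.poisson(lam)


def simulate_mixture(signatures: pd.DataFrame, reference: MarkerReference,
                     dirichlet_alpha, n_samples: int, depth: float = 2e6,
                     dispersion: float = 10.0, seed: int = 0):
    """Simulate bulk mixtures of cell-type signatures.

    ``signatures`` is a gene x cell-type table of expected expression
    profiles (each column is normalized internally). Per-sample mixing
    proportions are Dirichlet(alpha); bulk expected abundance is the
    proportion-weighted signature mix; counts come from
    :func:`simulate_counts`. Returns ``(matrix, true_proportions)`` with
    proportions as a sample x cell-type frame summing to 1 per row.
    """
    alpha = np.asarray(dirichlet_alpha, dtype=float)
    types = list(signatures.columns)
    if len(alpha) != len(types):
        raise ValueError(
            f"alpha length {len(alpha)} != number of cell types {len(types)}"
        )
    rng = np.random.default_rng(seed)
    sig = signatures.to_numpy(dtype=float)
    sig = sig / sig.sum(axis=0)
    props = rng.dirichlet(alpha, size=n_samples)         # samples x types
    counts = np.empty((signatures.shape[0], n_samples), dtype=np.int64)
    for j in range(n_samples):
        bulk = sig @ props[j]
        counts[:, j] = simulate_counts(bulk / bulk.sum(), depth, dispersion,
                                       1, rng)[:, 0]
    sample_ids = [f"mix{j + 1:03d}" for j in range(n_samples)]
    matrix = ExpressionMatrix(
        counts=pd.DataFrame(counts, index=signatures.index, columns=sample_ids),
        gene_lengths=pd.Series(1000.0, index=signatures.index),
    )
    matrix = tpm_from_counts(matrix)
    true_props = pd.DataFrame(props, index=sample_ids, columns=types)
    return matrix, true_props


def make_disjoint_signatures(n_types: int = 9, markers_per_type: int = 30,
                             n_background_genes: int = 500,
                             marker_level: float = 50.0, seed: int = 0):
    """Build disjoint per-cell-type signatures plus their marker reference.

    Each type expresses a shared log-normal background plus its own
    ``markers_per_type`` exclusive marker genes at ``marker_level`` times
    the mean background level.
    """
    rng = np.random.default_rng(seed)
    background = [f"bg{i + 1:04d}" for i in range(n_background_genes)]
    base = rng.lognormal(0.0, 1.0, n_background_genes)
    genes, markers = list(background), {}
    cols = {}
    for t in range(n_types):
        ct = f"type{t + 1}"
        m = [f"{ct}_mk{i + 1:02d}" for i in range(markers_per_type)]
        markers[ct] = m
        genes.extend(m)
    sig = pd.DataFrame(0.0, index=genes, columns=list(markers))
    for ct in markers:
        sig.loc[background, ct] = base
        sig.loc[markers[ct], ct] = marker_level * base.mean()
        cols[ct] = sig[ct]
    return sig, MarkerReference(markers=markers)


def generate_study(config: SimulationConfig):
    """End-to-end synthetic cohort: matrix + design + ground-truth record.

    Groups follow ``config.group_sizes`` and the severity ladder; the
    truth record lists the mechanism, severity, and affected genes per
    group. Counts and derived TPM are both populated.
    """
    rng = np.random.default_rng(config.seed)
    gene_ids = [f"gene{i + 1:05d}" for i in range(config.n_genes)]
    baseline = simulate_baseline(config, rng)

    columns, sample_ids, labels = [], [], []
    truth: dict = {"mechanism": config.mechanism, "seed": config.seed,
                   "groups": {}}
    for group, n in config.group_sizes.items():
        sev = config.severity.get(group, 0.0)
        perturbed, affected = apply_mechanism(baseline, config, sev, rng)
        counts = simulate_counts(perturbed, config.depth, config.dispersion,
                                 n, rng)
        columns.append(counts)
        ids = [f"{group}_{i + 1:02d}" for i in range(n)]
        sample_ids.extend(ids)
        labels.extend([group] * n)
        truth["groups"][group] = {
            "severity": sev,
            "n_samples": n,
            "affected_genes": [gene_ids[i] for i in np.flatnonzero(affected)],
        }

    counts_df = pd.DataFrame(np.hstack(columns), index=gene_ids,
                             columns=sample_ids)
    matrix = ExpressionMatrix(
        counts=counts_df,
        gene_lengths=pd.Series(config.gene_length, index=gene_ids,
                               dtype=float),
    )
    matrix = tpm_from_counts(matrix)
    design = GroupDesign(
        assignments=pd.Series(labels, index=sample_ids),
        groups=list(config.group_sizes),
        control=list(config.group_sizes)[0],
    )
    truth["config"] = config.to_dict()
    return matrix, design, truth
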