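"""Synthetic paired miRNA/mRNA case-control studies with planted truth.

The generator emulates the data model of a two-platform T-cell expression
study: a small-RNA array cohort (default 11 cases vs 9 controls) and an
mRNA array cohort (default 10 vs 9) drawn from overlapping but non-identical
participants, so the two matrices share group labels but not noise.

Generative model, all on the log2 scale:

* gene baselines ~ Normal(7, 1.5); per-gene noise variances sigma_g^2 are
  drawn from a scaled inverse chi-square, s0^2 * d0 / chi2(d0), so
  empirical-Bayes variance moderation has a recoverable prior;
* a chosen number of miRNAs are planted as down-regulated in cases with
  log2 fold changes delta_m drawn from a negative interval (defaults span
  the fold-change range 0.14-0.65 reported for T-cell miRNAs);
* each planted miRNA's predicted targets are de-repressed: target g of
  miRNA m gains a case-group mRNA shift of -beta_{m,g} * delta_m with
  transfer coefficients beta ~ Uniform(0, beta_max); effects from multiple
  regulators add.  The de-repression sign is configurable;
* additional independent DE genes (not explained by any miRNA) get their
  own shifts with random sign;
* two target-prediction maps emulate two databases: sizes ~ Poisson (mean
  200 targets per miRNA, truncated at >= 5); the second map resamples a
  configured fraction of each set and omits a configured fraction of miRNAs
  entirely (the "no predictions available" state);
* GO terms are random gene sets; designated enriched terms are seeded with
  an excess of strongly up-regulated planted genes;
* detection calls are Bernoulli per cell, forced true for planted miRNAs so
  the detection filter cannot remove planted signal.

Everything is drawn from one explicitly ordered stream of a single seeded
generator, so a config plus seed reproduces the study bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError, InputError
from .io import (
    DetectionMatrix,
    ExpressionMatrix,
    GeneSetCollection,
    TargetMap,
    write_detection_matrix,
    write_expression_matrix,
    write_gmt,
)
from .validation import PcrSampleRecord

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SyntheticStudy",
    "generate_study",
    "generate_pcr_dataset",
    "write_study",
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the emulated design."""

    # cohort sizes (miRNA arm and mRNA arm recruited separately)
    n_case: int = 11
    n_control: int = 9
    n_case_mrna: int = 10
    n_control_mrna: int = 9
    # platform sizes
    n_mirna: int = 1000
    n_gene: int = 20000
    # planted miRNA down-regulation
    n_de_mirna: int = 21
    mirna_log2fc_range: tuple[float, float] = (-2.8, -0.6)
    mirna_baseline_mean: float = 6.0
    mirna_baseline_sd: float = 1.0
    mirna_sigma: float = 0.6
    # target structure and repression transfer
    targets_per_mirna_mean: float = 200.0
    repression_transfer_max: float = 0.5  # beta_max
    derepression: bool = True  # down-regulated miRNA -> UP-shifted targets
    map2_resample_fraction: float = 0.3
    map2_absent_fraction: float = 0.2
    # mRNA noise model
    gene_baseline_mean: float = 7.0
    gene_baseline_sd: float = 1.5
    prior_df: float = 4.0  # d0
    prior_scale: float = 0.05  # s0^2
    # DE genes not explained by miRNAs
    n_de_gene_independent: int = 200
    independent_effect_range: tuple[float, float] = (0.5, 2.0)
    # detection calls
    detection_prob: float = 0.9
    # GO annotation
    n_go_terms: int = 100
    go_term_size_range: tuple[int, int] = (10, 100)
    n_enriched_terms: int = 5
    enriched_member_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_case": self.n_case,
            "n_control": self.n_control,
            "n_case_mrna": self.n_case_mrna,
            "n_control_mrna": self.n_control_mrna,
            "n_mirna": self.n_mirna,
            "n_gene": self.n_gene,
        }
        for name, v in counts.items():
            if v < 1:
                raise ConfigError(f"{name} must be positive")
        if self.n_de_mirna > self.n_mirna:
            raise ConfigError("n_de_mirna exceeds n_mirna")
        if self.n_de_mirna < 0 or self.n_de_gene_independent < 0:
            raise ConfigError("planted counts must be non-negative")
        if self.repression_transfer_max < 0:
            raise ConfigError("repression transfer beta_max must be >= 0")
        lo, hi = self.mirna_log2fc_range
        if self.n_de_mirna > 0 and not (lo <= hi <= 0):
            raise ConfigError("mirna_log2fc_range must be a non-positive interval")
        if not (self.prior_df > 0 and self.prior_scale > 0):
            raise ConfigError("variance prior parameters must be positive")
        if not (0 < self.detection_prob <= 1):
            raise ConfigError("detection_prob must lie in (0, 1]")
        if self.go_term_size_range[1] > self.n_gene:
            raise ConfigError("GO term sizes exceed the gene universe")
        if self.n_enriched_terms > self.n_go_terms:
            raise ConfigError("n_enriched_terms exceeds n_go_terms")
        if self.targets_per_mirna_mean <= 0:
            raise ConfigError("targets_per_mirna_mean must be positive")


@dataclass
class SyntheticTruth:
    """Planted structure needed for recovery testing."""

    de_mirnas: dict[str, float]  # miRNA -> planted log2 fold change (negative)
    target_map: TargetMap  # the true regulatory map (source A)
    transfer: dict[str, dict[str, float]]  # miRNA -> gene -> beta
    de_genes_independent: dict[str, float]  # gene -> planted log2 effect
    gene_sd: dict[str, float]  # gene -> noise sd sigma_g
    enriched_go_terms: set[str] = field(default_factory=set)

    def planted_gene_effects(self) -> dict[str, float]:
        """Total planted case-group log2 shift per gene (targets + independent)."""
        eff: dict[str, float] = {}
        for mirna, delta in self.de_mirnas.items():
            for gene, beta in self.transfer.get(mirna, {}).items():
                eff[gene] = eff.get(gene, 0.0) - beta * delta
        for gene, e in self.de_genes_independent.items():
            eff[gene] = eff.get(gene, 0.0) + e
        return eff


@dataclass
class SyntheticStudy:
    mirna_expr: ExpressionMatrix
    mrna_expr: ExpressionMatrix
    mirna_detection: DetectionMatrix
    target_maps: tuple[TargetMap, TargetMap]
    go: GeneSetCollection
    truth: SyntheticTruth
    config: SimulationConfig


def _target_sizes(rng: np.random.Generator, n: int, mean: float, n_gene: int) -> np.ndarray:
    sizes = rng.poisson(mean, size=n)
    redo = sizes < 5
    if redo.any():
        sizes[redo] = np.maximum(rng.poisson(mean, size=int(redo.sum())), 5)
    if (sizes >= n_gene).any():
        raise ConfigError("target set size reaches the gene universe; no background left")
    return sizes


def generate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate one synthetic study; deterministic given the config seed."""
    rng = np.random.default_rng(config.seed)
    gene_ids = [f"G{i:05d}" for i in range(config.n_gene)]
    mirna_ids = [f"sim-miR-{i:04d}" for i in range(config.n_mirna)]

    # --- planted miRNA effects (draw order is part of the contract) -------
    de_idx = rng.choice(config.n_mirna, size=config.n_de_mirna, replace=False)
    lo, hi = config.mirna_log2fc_range
    deltas = rng.uniform(lo, hi, size=config.n_de_mirna)
    de_mirnas = {mirna_ids[i]: float(d) for i, d in zip(de_idx, deltas)}

    # --- target maps -------------------------------------------------------
    sizes = _target_sizes(rng, config.n_mirna, config.targets_per_mirna_mean, config.n_gene)
    map_a: dict[str, frozenset[str]] = {}
    for mirna, k in zip(mirna_ids, sizes):
        idx = rng.choice(config.n_gene, size=int(k), replace=False)
        map_a[mirna] = frozenset(gene_ids[i] for i in idx)
    map_b: dict[str, frozenset[str]] = {}
    for mirna in mirna_ids:
        absent = rng.random() < config.map2_absent_fraction
        genes = sorted(map_a[mirna])
        n_resample = int(round(config.map2_resample_fraction * len(genes)))
        keep = list(rng.choice(len(genes), size=len(genes) - n_resample, replace=False))
        fresh = rng.choice(config.n_gene, size=n_resample, replace=False)
        if absent:
            continue
        members = {genes[i] for i in keep} | {gene_ids[i] for i in fresh}
        map_b[mirna] = frozenset(members)
    targets_a = TargetMap("simTargetsA", map_a)
    targets_b = TargetMap("simTargetsB", map_b)

    # --- repression transfer onto target genes ----------------------------
    sign = 1.0 if config.derepression else -1.0
    transfer: dict[str, dict[str, float]] = {}
    gene_effect = np.zeros(config.n_gene)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    for mirna in mirna_ids:
        if mirna not in de_mirnas:
            continue
        delta = de_mirnas[mirna]
        genes = sorted(map_a[mirna])
        betas = rng.uniform(0.0, config.repression_transfer_max, size=len(genes))
        transfer[mirna] = dict(zip(genes, betas.astype(float)))
        for g, b in zip(genes, betas):
            gene_effect[gene_pos[g]] += sign * (-b * delta)

    # --- independent DE genes ---------------------------------------------
    ind_idx = rng.choice(config.n_gene, size=config.n_de_gene_independent, replace=False)
    elo, ehi = config.independent_effect_range
    magnitudes = rng.uniform(elo, ehi, size=config.n_de_gene_independent)
    signs = rng.choice([-1.0, 1.0], size=config.n_de_gene_independent)
    de_genes_independent = {}
    for i, mag, s in zip(ind_idx, magnitudes, signs):
        de_genes_independent[gene_ids[i]] = float(mag * s)
        gene_effect[i] += mag * s

    # --- mRNA matrix -------------------------------------------------------
    n1, n2 = config.n_case_mrna, config.n_control_mrna
    baselines = rng.normal(config.gene_baseline_mean, config.gene_baseline_sd, size=config.n_gene)
    sigma_sq = config.prior_scale * config.prior_df / rng.chisquare(config.prior_df, size=config.n_gene)
    sigma = np.sqrt(sigma_sq)
    noise = rng.standard_normal((config.n_gene, n1 + n2)) * sigma[:, None]
    mrna_values = baselines[:, None] + noise
    mrna_values[:, :n1] += gene_effect[:, None]
    mrna_samples = [f"ms{i+1:02d}" for i in range(n1)] + [f"hc{i+1:02d}" for i in range(n2)]
    mrna_groups = {s: ("case" if i < n1 else "control") for i, s in enumerate(mrna_samples)}
    mrna_expr = ExpressionMatrix(gene_ids, mrna_samples, mrna_values, mrna_groups)

    # --- miRNA matrix (independent cohort noise) ---------------------------
    m1, m2 = config.n_case, config.n_control
    mirna_base = rng.normal(config.mirna_baseline_mean, config.mirna_baseline_sd, size=config.n_mirna)
    mirna_values = mirna_base[:, None] + rng.standard_normal((config.n_mirna, m1 + m2)) * config.mirna_sigma
    mirna_shift = np.zeros(config.n_mirna)
    for i, mirna in enumerate(mirna_ids):
        if mirna in de_mirnas:
            mirna_shift[i] = de_mirnas[mirna]
    mirna_values[:, :m1] += mirna_shift[:, None]
    mirna_samples = [f"msM{i+1:02d}" for i in range(m1)] + [f"hcM{i+1:02d}" for i in range(m2)]
    mirna_groups = {s: ("case" if i < m1 else "control") for i, s in enumerate(mirna_samples)}
    mirna_expr = ExpressionMatrix(mirna_ids, mirna_samples, mirna_values, mirna_groups)

    # --- detection calls ----------------------------------------------------
    detected = rng.random((config.n_mirna, m1 + m2)) < config.detection_prob
    for i, mirna in enumerate(mirna_ids):
        if mirna in de_mirnas:
            detected[i, :] = True
    detection = DetectionMatrix(mirna_ids, list(mirna_samples), detected)

    # --- GO annotation ------------------------------------------------------
    slo, shi = config.go_term_size_range
    up_pool = sorted(
        g for g, e in zip(gene_ids, gene_effect) if e >= 0.5
    )
    if config.n_enriched_terms > 0 and not up_pool:
        raise ConfigError("cannot seed enriched GO terms: no strongly up-regulated planted genes")
    go_sets: dict[str, tuple[str, frozenset[str]]] = {}
    enriched: set[str] = set()
    for t in range(config.n_go_terms):
        term = f"GO:{t+1:07d}"
        size = int(rng.integers(slo, shi + 1))
        if t < config.n_enriched_terms:
            n_seed = min(len(up_pool), max(1, int(round(config.enriched_member_fraction * size))))
            seed_idx = rng.choice(len(up_pool), size=n_seed, replace=False)
            members = {up_pool[i] for i in seed_idx}
            rest = rng.choice(config.n_gene, size=size, replace=False)
            for i in rest:
                if len(members) >= size:
                    break
                members.add(gene_ids[i])
            enriched.add(term)
        else:
            idx = rng.choice(config.n_gene, size=size, replace=False)
            members = {gene_ids[i] for i in idx}
        go_sets[term] = (f"synthetic term {t+1}", frozenset(members))
    go = GeneSetCollection(go_sets, ontology_label="synthetic-GO")

    truth = SyntheticTruth(
        de_mirnas=de_mirnas,
        target_map=targets_a,
        transfer=transfer,
        de_genes_independent=de_genes_independent,
        gene_sd={g: float(s) for g, s in zip(gene_ids, sigma)},
        enriched_go_terms=enriched,
    )
    return SyntheticStudy(
        mirna_expr=mirna_expr,
        mrna_expr=mrna_expr,
        mirna_detection=detection,
        target_maps=(targets_a, targets_b),
        go=go,
        truth=truth,
        config=config,
    )


def generate_pcr_dataset(
    n_case: int,
    n_control: int,
    true_log2_ratio: float,
    sd: float,
    seed: int = 0,
) -> list[PcrSampleRecord]:
    """Synthetic qPCR Ct table with a planted case/control expression ratio.

    The case group's dCt is shifted by -true_log2_ratio (one PCR cycle per
    doubling).  A per-sample offset is added to both Ct values to emulate
    input-amount variation; the reference-gene subtraction cancels it.
    Measurement noise of standard deviation ``sd`` applies to the target Ct.
    """
    if sd < 0:
        raise InputError("Ct noise sd must be >= 0")
    if n_case < 1 or n_control < 1:
        raise InputError("need at least one sample per group")
    rng = np.random.default_rng(seed)
    records: list[PcrSampleRecord] = []
    base_dct = 5.0
    for i in range(n_case + n_control):
        group = "case" if i < n_case else "control"
        offset = rng.uniform(-1.0, 1.0)
        shift = -true_log2_ratio if group == "case" else 0.0
        ct_ref = 20.0 + offset
        ct_tgt = 20.0 + base_dct + shift + offset + rng.normal(0.0, sd) if sd > 0 else 20.0 + base_dct + shift + offset
        records.append(PcrSampleRecord(f"{group[0]}{i+1:02d}", group, float(ct_tgt), float(ct_ref)))
    return records


def write_study(study: SyntheticStudy, out_dir: str | Path) -> None:
    """Write the study as the pipeline's text formats plus truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression_matrix(study.mirna_expr, out / "mirna_expr.tsv", out / "mirna_samples.csv")
    write_expression_matrix(study.mrna_expr, out / "mrna_expr.tsv", out / "mrna_samples.csv")
    write_detection_matrix(study.mirna_detection, out / "mirna_detection.tsv")
    write_gmt(study.target_maps[0], out / "targets_a.gmt")
    write_gmt(study.target_maps[1], out / "targets_b.gmt")
    write_gmt(study.go, out / "go.gmt")
    truth = study.truth
    payload = {
        "de_mirnas": dict(sorted(truth.de_mirnas.items())),
        "transfer": {m: dict(sorted(d.items())) for m, d in sorted(truth.transfer.items())},
        "de_genes_independent": dict(sorted(truth.de_genes_independent.items())),
        "gene_sd": dict(sorted(truth.gene_sd.items())),
        "enriched_go_terms": sorted(truth.enriched_go_terms),
        "config": asdict(study.config),
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
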