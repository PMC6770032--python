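"""Synthetic cohorts with planted age correlations and miRNA->target repression.

The generator emulates the statistical structure of a paired miRNA / gene
expression study of a pediatric-to-young-adult tumor cohort: continuous ages
at day resolution (hence tie-free), a minority of features whose expression
tracks age monotonically, a subset of those correlated in tumor tissue only,
and a planted repression map in which selected miRNAs monotonically suppress
designated target genes.  Everything else is i.i.d. Gaussian noise on a
per-feature baseline.

Planted-signal calibration
--------------------------
A planted feature is ``baseline + noise_sd * (r * g(age) + sqrt(1-r^2) * eps)``
where ``g`` maps ages to normal scores (a rank-preserving transform, so the
choice is immaterial to Spearman) and ``eps`` is standard normal.  The pair
``(feature, age)`` is then bivariate normal on the latent scale with Pearson
correlation ``r``, whose population Spearman correlation is
``(6/pi) * arcsin(r/2)``.  Inverting, ``r = 2 * sin(pi * rho_s / 6)`` plants
an expected sample Spearman of ``rho_s`` in closed form — no empirical noise
calibration is needed.  Repressed target genes use the same construction with
a negative sign against their miRNA's normal scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from math import pi, sin
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import (
    ExpressionMatrix,
    SampleRecord,
    TargetTable,
    write_expression,
    write_samples,
    write_targets,
)

__all__ = [
    "SimulationConfig",
    "PlantedFeature",
    "GroundTruth",
    "SimulatedCohort",
    "simulate_cohort",
    "write_cohort",
]

#: Fixed diagnosis date for all simulated samples; birth dates are back-dated
#: so the derived age reproduces the simulated age exactly at day resolution.
_DIAGNOSIS_DATE = date(2019, 1, 1)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the simulated cohort.

    Defaults mirror the emulated study: 49 tumor + 15 non-neoplastic samples,
    1,710 miRNAs, 18,531 genes, ages spanning early childhood to the
    mid-thirties, 39 positively / 20 negatively age-correlated features and
    10 tumor-only candidates per matrix.
    """

    n_tumor: int = 49
    n_normal: int = 15
    n_mirna: int = 1710
    n_gene: int = 18531
    n_planted_pos: int = 39
    n_planted_neg: int = 20
    n_tumor_only: int = 10
    targets_per_mirna: float = 40.0
    planted_rho: float = 0.6
    repression_strength: float = 0.6
    noise_sd: float = 1.0
    age_range_years: tuple = (1.0, 35.0)
    seed: int = 0

    def __post_init__(self):
        counts = {
            "n_tumor": self.n_tumor,
            "n_normal": self.n_normal,
            "n_mirna": self.n_mirna,
            "n_gene": self.n_gene,
            "n_planted_pos": self.n_planted_pos,
            "n_planted_neg": self.n_planted_neg,
            "n_tumor_only": self.n_tumor_only,
        }
        for name, value in counts.items():
            if value < 0:
                raise ValueError(f"invariant violated: {name} must be >= 0, got {value}")
        n_planted = self.n_planted_pos + self.n_planted_neg + self.n_tumor_only
        if n_planted > self.n_mirna:
            raise ValueError(
                "invariant violated: n_planted_pos + n_planted_neg + n_tumor_only "
                f"({n_planted}) exceeds n_mirna ({self.n_mirna})"
            )
        if n_planted > self.n_gene:
            raise ValueError(
                "invariant violated: n_planted_pos + n_planted_neg + n_tumor_only "
                f"({n_planted}) exceeds n_gene ({self.n_gene})"
            )
        if not 0.0 < self.planted_rho <= 1.0:
            raise ValueError(
                f"invariant violated: planted_rho must be in (0, 1], got {self.planted_rho}"
            )
        if not 0.0 < self.repression_strength <= 1.0:
            raise ValueError(
                "invariant violated: repression_strength must be in (0, 1], "
                f"got {self.repression_strength}"
            )
        if self.noise_sd < 0:
            raise ValueError(
                f"invariant violated: noise_sd must be >= 0, got {self.noise_sd}"
            )
        lo, hi = self.age_range_years
        if not lo < hi:
            raise ValueError(
                f"invariant violated: age range min must be < max, got {self.age_range_years}"
            )
        if self.targets_per_mirna < 0:
            raise ValueError(
                f"invariant violated: targets_per_mirna must be >= 0, got {self.targets_per_mirna}"
            )

    @staticmethod
    def cohort_scale(seed: int = 0, **overrides) -> "SimulationConfig":
        """Full-scale preset (the emulated study's dimensions)."""
        return SimulationConfig(seed=seed, **overrides)

    @staticmethod
    def reduced(seed: int = 0, **overrides) -> "SimulationConfig":
        """Scaled-down preset for fast tests: 200 miRNAs, 2,000 genes."""
        defaults = dict(
            n_mirna=200,
            n_gene=2000,
            n_planted_pos=20,
            n_planted_neg=10,
            n_tumor_only=10,
            targets_per_mirna=20.0,
        )
        defaults.update(overrides)
        return SimulationConfig(seed=seed, **defaults)


@dataclass(frozen=True)
class PlantedFeature:
    feature_id: str
    kind: str            # mirna | gene
    sign: int            # +1 | -1
    scope: str           # both | tumor_only


@dataclass(frozen=True)
class GroundTruth:
    """What was planted: age-correlated features and repression pairs."""

    planted: tuple
    repression_pairs: frozenset

    def ids(self, kind: str, scope: str | None = None, sign: int | None = None):
        return frozenset(
            f.feature_id
            for f in self.planted
            if f.kind == kind
            and (scope is None or f.scope == scope)
            and (sign is None or f.sign == sign)
        )

    def validate(self, mirna: ExpressionMatrix, gene: ExpressionMatrix, targets: TargetTable):
        universe = {"mirna": set(mirna.feature_ids), "gene": set(gene.feature_ids)}
        for f in self.planted:
            if f.feature_id not in universe[f.kind]:
                raise AssertionError(f"planted id missing from matrix: {f.feature_id}")
        missing = self.repression_pairs - targets.pairs
        if missing:
            raise AssertionError(f"repression pairs missing from target table: {missing}")

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted": [asdict(f) for f in self.planted],
                "repression_pairs": sorted(map(list, self.repression_pairs)),
            },
            indent=1,
        )

    @staticmethod
    def from_json(text: str) -> "GroundTruth":
        obj = json.loads(text)
        return GroundTruth(
            planted=tuple(PlantedFeature(**f) for f in obj["planted"]),
            repression_pairs=frozenset(tuple(p) for p in obj["repression_pairs"]),
        )


@dataclass(frozen=True)
class SimulatedCohort:
    mirna: ExpressionMatrix
    gene: ExpressionMatrix
    samples: tuple
    targets: TargetTable
    truth: GroundTruth
    config: SimulationConfig

    def __iter__(self):
        return iter((self.mirna, self.gene, self.samples, self.targets, self.truth))


def _normal_scores(values: np.ndarray) -> np.ndarray:
    """Blom normal scores: a rank-preserving map to ~N(0,1)."""
    n = len(values)
    ranks = stats.rankdata(values)
    return stats.norm.ppf((ranks - 0.375) / (n + 0.25))


def _mix(g: np.ndarray, eps: np.ndarray, rho_s: float, sign: int) -> np.ndarray:
    r = 2.0 * sin(pi * rho_s / 6.0)
    return sign * r * g + np.sqrt(1.0 - r * r) * eps


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a cohort with planted structure; deterministic given the seed.

    All randomness flows from one master seed through fixed-index child
    streams, so any sub-component is reproducible independently of the
    others.  Ages are drawn at day resolution without replacement and are
    therefore strictly distinct.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_age, rng_mirna, rng_gene, rng_targets = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]

    n_samples = config.n_tumor + config.n_normal
    lo, hi = config.age_range_years
    day_grid = np.arange(int(round(lo * 365)), int(round(hi * 365)))
    if len(day_grid) < n_samples:
        raise ValueError("age range too narrow for distinct day-resolution ages")
    days = rng_age.choice(day_grid, size=n_samples, replace=False)
    ages = days / 365.0

    sample_ids = [f"T{i + 1:03d}" for i in range(config.n_tumor)] + [
        f"N{i + 1:03d}" for i in range(config.n_normal)
    ]
    tissues = ["tumor"] * config.n_tumor + ["normal"] * config.n_normal
    samples = tuple(
        SampleRecord.create(
            sid,
            _DIAGNOSIS_DATE - timedelta(days=int(d)),
            _DIAGNOSIS_DATE,
            tissue,
        )
        for sid, d, tissue in zip(sample_ids, days, tissues)
    )

    tumor_idx = np.arange(config.n_tumor)
    normal_idx = np.arange(config.n_tumor, n_samples)
    g_all = _normal_scores(ages)
    g_tumor = _normal_scores(ages[tumor_idx])

    def build_matrix(kind, n_features, rng):
        ids = [
            (f"mir-{i + 1:04d}" if kind == "mirna" else f"gene-{i + 1:05d}")
            for i in range(n_features)
        ]
        baseline = rng.uniform(6.0, 14.0, size=n_features)
        values = baseline[:, None] + config.noise_sd * rng.standard_normal(
            (n_features, n_samples)
        )
        planted = []
        row = 0
        for sign, count in ((+1, config.n_planted_pos), (-1, config.n_planted_neg)):
            for _ in range(count):
                eps = rng.standard_normal(n_samples)
                values[row] = baseline[row] + config.noise_sd * _mix(
                    g_all, eps, config.planted_rho, sign
                )
                planted.append(PlantedFeature(ids[row], kind, sign, "both"))
                row += 1
        for k in range(config.n_tumor_only):
            sign = +1 if k % 2 == 0 else -1
            eps_t = rng.standard_normal(config.n_tumor)
            values[row, tumor_idx] = baseline[row] + config.noise_sd * _mix(
                g_tumor, eps_t, config.planted_rho, sign
            )
            # normal columns stay pure noise (already drawn)
            planted.append(PlantedFeature(ids[row], kind, sign, "tumor_only"))
            row += 1
        return ids, values, planted

    mirna_ids, mirna_values, mirna_planted = build_matrix(
        "mirna", config.n_mirna, rng_mirna
    )
    gene_ids, gene_values, gene_planted = build_matrix("gene", config.n_gene, rng_gene)

    # --- planted repression: tumor-only miRNAs suppress reserved background genes
    n_planted_gene = len(gene_planted)
    background_genes = list(range(n_planted_gene, config.n_gene))
    candidate_mirnas = [f.feature_id for f in mirna_planted if f.scope == "tumor_only"]
    pairs = []
    repression_pairs = set()
    pool = iter(background_genes)
    n_rep = max(1, int(round(config.targets_per_mirna / 2))) if candidate_mirnas else 0
    for m_idx, mirna_id in enumerate(candidate_mirnas):
        m_row = mirna_ids.index(mirna_id)
        zt = _normal_scores(mirna_values[m_row, tumor_idx])
        zn = (
            _normal_scores(mirna_values[m_row, normal_idx])
            if config.n_normal >= 2
            else np.zeros(config.n_normal)
        )
        for _ in range(n_rep):
            try:
                g_row = next(pool)
            except StopIteration:
                break
            eps_t = rng_targets.standard_normal(config.n_tumor)
            eps_n = rng_targets.standard_normal(config.n_normal)
            gene_values[g_row, tumor_idx] = gene_values[g_row, tumor_idx].mean() + (
                config.noise_sd
                * _mix(zt, eps_t, config.repression_strength, -1)
            )
            gene_values[g_row, normal_idx] = gene_values[g_row, normal_idx].mean() + (
                config.noise_sd
                * _mix(zn, eps_n, config.repression_strength, -1)
            )
            pairs.append((mirna_id, gene_ids[g_row]))
            repression_pairs.add((mirna_id, gene_ids[g_row]))

    # decoy targets: independent-noise genes, so only the planted pairs should
    # survive the anti-correlation filter beyond the nominal false-edge rate
    n_decoy = max(0, int(round(config.targets_per_mirna)) - n_rep)
    decoy_universe = [gene_ids[i] for i in background_genes[len(repression_pairs):]]
    planted_mirna_ids = [f.feature_id for f in mirna_planted]
    for mirna_id in planted_mirna_ids:
        k = n_decoy if mirna_id in candidate_mirnas else int(round(config.targets_per_mirna))
        if k <= 0 or not decoy_universe:
            continue
        chosen = rng_targets.choice(
            len(decoy_universe), size=min(k, len(decoy_universe)), replace=False
        )
        pairs.extend((mirna_id, decoy_universe[j]) for j in chosen)

    targets = TargetTable.from_pairs(pairs) if pairs else TargetTable({}, 0)
    truth = GroundTruth(
        planted=tuple(mirna_planted + gene_planted),
        repression_pairs=frozenset(repression_pairs),
    )

    mirna = ExpressionMatrix(
        pd.DataFrame(mirna_values, index=mirna_ids, columns=sample_ids), "mirna"
    )
    gene = ExpressionMatrix(
        pd.DataFrame(gene_values, index=gene_ids, columns=sample_ids), "gene"
    )
    truth.validate(mirna, gene, targets)
    return SimulatedCohort(mirna, gene, samples, targets, truth, config)


def write_cohort(cohort: SimulatedCohort, outdir) -> dict:
    """Write the five cohort files; returns {name: path}."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mirna": outdir / "mirna_expression.tsv",
        "gene": outdir / "gene_expression.tsv",
        "samples": outdir / "samples.tsv",
        "targets": outdir / "targets.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_expression(cohort.mirna, paths["mirna"])
    write_expression(cohort.gene, paths["gene"])
    write_samples(cohort.samples, paths["samples"])
    write_targets(cohort.targets, paths["targets"])
    paths["ground_truth"].write_text(cohort.truth.to_json())
    return paths
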