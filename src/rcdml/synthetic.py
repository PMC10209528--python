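"""Self-contained synthetic cohorts with known ground truth.

The generator emulates the two inputs the pipeline consumes: a CPM expression
matrix and a per-inhibitor drug-response table.  Each sample carries a latent
response score drawn from a skew-normal (the skew emulates the left/right
skewed drug-AUC histograms seen in real ex vivo panels); the drug AUC is an
affine transform of that latent score plus noise, and each informative gene's
log2-CPM is shifted by ``effect_size`` times the standardised latent score.
Expression is log-normal on the CPM scale — the pipeline's inputs are already
library-size normalised, so a continuous generative model suffices; no
attempt is made to reproduce count noise or the gene-gene correlation
structure of real cohorts.

Informative genes are planted on well-expressed baselines (log2-CPM mean
drawn from N(4, 1)); a "signal" gene sitting below the expression filter
would be undetectable by construction rather than by method failure, which
is not the regime the pipeline is meant to probe.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import DrugResponseTable, ExpressionMatrix

__all__ = ["SyntheticSpec", "CohortTruth", "generate_cohort", "generate_multi_inhibitor"]

AUC_CENTER = 150.0  # typical centre of ex vivo dose-response AUC scales
AUC_SCALE = 40.0  # latent-score to AUC slope


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic inhibitor cohort.

    ``effect_size`` is the mean log2-CPM shift per informative gene per unit
    of standardised latent response; ``response_skew`` is the skew-normal
    shape of the latent (and hence drug-AUC) distribution; ``noise_sd`` is
    the AUC measurement noise on the AUC scale; ``dispersion`` is the
    per-gene log2-CPM standard deviation.
    """

    n_samples: int = 300
    n_genes: int = 20000
    n_informative: int = 10
    effect_size: float = 2.0
    dispersion: float = 1.0
    response_skew: float = 0.0
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_genes:
            raise ValueError("n_informative exceeds n_genes")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.n_samples < 4:
            raise ValueError("need at least 4 samples")


@dataclass
class CohortTruth:
    inhibitor: str
    informative_genes: list[str]
    latent: dict[str, float]  # sample -> standardised latent response score
    spec: SyntheticSpec

    def to_json(self, path: str | Path) -> None:
        payload = {
            "inhibitor": self.inhibitor,
            "informative_genes": self.informative_genes,
            "latent": self.latent,
            "spec": asdict(self.spec),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            inhibitor=d["inhibitor"],
            informative_genes=d["informative_genes"],
            latent=d["latent"],
            spec=SyntheticSpec(**d["spec"]),
        )


def _standardised_skewnorm(rng: np.random.Generator, a: float, n: int) -> np.ndarray:
    z = stats.skewnorm.rvs(a=a, size=n, random_state=rng)
    return (z - z.mean()) / z.std()


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _sample_ids(n: int) -> list[str]:
    return [f"S{i:04d}" for i in range(n)]


def _build_expression(
    rng: np.random.Generator,
    spec: SyntheticSpec,
    genes: list[str],
    samples: list[str],
    shifts: Mapping[str, np.ndarray],
) -> ExpressionMatrix:
    """Log-normal CPM baseline plus per-informative-gene latent-driven shifts."""
    n_genes, n_samples = len(genes), len(samples)
    mu = rng.normal(3.0, 2.0, size=n_genes)
    informative_idx = {g: i for i, g in enumerate(genes)}
    log2cpm = mu[:, None] + rng.normal(0.0, spec.dispersion, size=(n_genes, n_samples))
    for gene, shift in shifts.items():
        i = informative_idx[gene]
        log2cpm[i] = rng.normal(4.0, 1.0) + shift + rng.normal(
            0.0, spec.dispersion, size=n_samples
        )
    cpm = np.exp2(log2cpm)
    return ExpressionMatrix(pd.DataFrame(cpm, index=genes, columns=samples))


def generate_cohort(
    spec: SyntheticSpec, inhibitor: str = "SYN-1"
) -> tuple[ExpressionMatrix, DrugResponseTable, CohortTruth]:
    """One inhibitor's cohort: expression, responses and the planted truth."""
    rng = np.random.default_rng(spec.seed)
    genes = _gene_ids(spec.n_genes)
    samples = _sample_ids(spec.n_samples)

    z = _standardised_skewnorm(rng, spec.response_skew, spec.n_samples)
    auc = AUC_CENTER + AUC_SCALE * z + rng.normal(0.0, spec.noise_sd, spec.n_samples)
    auc = np.clip(auc, 0.0, None)

    informative = sorted(rng.choice(spec.n_genes, size=spec.n_informative, replace=False))
    informative_genes = [genes[i] for i in informative]
    shifts = {g: spec.effect_size * z for g in informative_genes}

    expr = _build_expression(rng, spec, genes, samples, shifts)
    resp = DrugResponseTable(
        pd.DataFrame(
            {
                "sample_id": samples,
                "inhibitor": inhibitor,
                "response_auc": auc,
                "ic50": np.nan,
            }
        )
    )
    truth = CohortTruth(
        inhibitor=inhibitor,
        informative_genes=informative_genes,
        latent=dict(zip(samples, map(float, z))),
        spec=spec,
    )
    return expr, resp, truth


def generate_multi_inhibitor(
    specs: Mapping[str, SyntheticSpec],
    shared_expression: bool = True,
    informative_sets: Mapping[str, Sequence[str]] | None = None,
) -> tuple[ExpressionMatrix, DrugResponseTable, dict[str, CohortTruth]]:
    """Several inhibitors over one expression matrix, each with its own signal.

    With ``shared_expression`` all specs must agree on ``n_genes``; the
    expression matrix covers the union of samples (``max n_samples``), each
    inhibitor's responses cover a seeded subsample of its own size, and each
    inhibitor drives its own informative gene set.  By default the sets are
    drawn disjoint; pass ``informative_sets`` to plant specific (possibly
    shared) genes per inhibitor.
    """
    if not specs:
        raise ValueError("no specs given")
    items = list(specs.items())
    n_genes = items[0][1].n_genes
    if shared_expression and any(s.n_genes != n_genes for _, s in items):
        raise ValueError("shared expression requires equal n_genes across specs")
    if not shared_expression:
        raise NotImplementedError("only shared-expression generation is supported")

    n_total = max(s.n_samples for _, s in items)
    genes = _gene_ids(n_genes)
    samples = _sample_ids(n_total)

    base_rng = np.random.default_rng(items[0][1].seed)
    mu = base_rng.normal(3.0, 2.0, size=n_genes)
    log2cpm = mu[:, None] + base_rng.normal(
        0.0, items[0][1].dispersion, size=(n_genes, n_total)
    )

    records = []
    truths: dict[str, CohortTruth] = {}
    claimed: set[int] = set()
    for name, spec in items:
        rng = np.random.default_rng(spec.seed)
        z_full = _standardised_skewnorm(rng, spec.response_skew, n_total)
        if informative_sets is not None and name in informative_sets:
            informative_genes = list(informative_sets[name])
            if len(informative_genes) != spec.n_informative:
                raise ValueError(
                    f"informative set for {name!r} has {len(informative_genes)} genes, "
                    f"spec says {spec.n_informative}"
                )
            missing = [g for g in informative_genes if g not in genes]
            if missing:
                raise ValueError(f"unknown informative genes for {name!r}: {missing}")
            idx = sorted(genes.index(g) for g in informative_genes)
        else:
            free = [i for i in range(n_genes) if i not in claimed]
            pick = rng.choice(len(free), size=spec.n_informative, replace=False)
            idx = sorted(free[i] for i in pick)
        informative_genes = [genes[i] for i in idx]
        for i in idx:
            if i not in claimed:
                # re-seat the planted gene on a well-expressed baseline once
                log2cpm[i] = rng.normal(4.0, 1.0) + rng.normal(
                    0.0, spec.dispersion, size=n_total
                )
            log2cpm[i] = log2cpm[i] + spec.effect_size * z_full
        claimed.update(idx)
        cohort_idx = np.sort(rng.choice(n_total, size=spec.n_samples, replace=False))
        auc = (
            AUC_CENTER
            + AUC_SCALE * z_full[cohort_idx]
            + rng.normal(0.0, spec.noise_sd, spec.n_samples)
        )
        auc = np.clip(auc, 0.0, None)
        cohort_samples = [samples[i] for i in cohort_idx]
        records.append(
            pd.DataFrame(
                {
                    "sample_id": cohort_samples,
                    "inhibitor": name,
                    "response_auc": auc,
                    "ic50": np.nan,
                }
            )
        )
        truths[name] = CohortTruth(
            inhibitor=name,
            informative_genes=informative_genes,
            latent=dict(zip(cohort_samples, map(float, z_full[cohort_idx]))),
            spec=spec,
        )

    expr = ExpressionMatrix(pd.DataFrame(np.exp2(log2cpm), index=genes, columns=samples))
    resp = DrugResponseTable(pd.concat(records, ignore_index=True))
    return expr, resp, truths
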