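"""Synthetic cohorts with planted subtype structure.

Stands in for a real exome-sequenced tumor cohort plus interaction network.
The generator plants the structure the stratification method assumes:

* a modular gene network (planted-partition graph) whose communities act
  as pathways; within-community edges are dense and confident, between-
  community edges sparse and weak;
* sparse binary mutation profiles in which each patient's subtype mutates
  genes of one community at a `driver` rate and all other genes at a low
  `background` rate — so same-subtype patients rarely share exact genes
  but hit the same community;
* gene panels enriched for community (driver) genes plus decoy genes;
* exponential survival with subtype-specific hazards and independent
  exponential censoring.

Ground truth (subtype per sample, module per gene, hazard per subtype) is
returned alongside every artifact for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import BinaryMutationMatrix, GenePanel
from .network_ops import GeneNetwork

__all__ = [
    "SyntheticTruth",
    "gen_network",
    "gen_cohort",
    "gen_panel",
    "gen_clinical",
    "cohort_to_mutation_table",
    "write_simulation",
]

# Study-condition defaults: a modular network with clear communities and a
# cohort whose per-sample driver signal (~0.2 x module size genes) stands
# over a ~1% gene background, mirroring the sparse-mutation regime the
# method targets.
DEFAULT_P_IN = 0.3
DEFAULT_P_OUT = 0.02
DEFAULT_DRIVER_RATE = 0.2
DEFAULT_BACKGROUND_RATE = 0.01


@dataclass
class SyntheticTruth:
    """Planted ground truth for one simulated study."""

    subtype_of: dict[str, int] = field(default_factory=dict)
    module_of: dict[str, int] = field(default_factory=dict)
    hazard_of: dict[int, float] = field(default_factory=dict)
    seed: int = 0

    def subtype_labels(self, samples: list[str]) -> np.ndarray:
        return np.array([self.subtype_of[s] for s in samples])

    def module_genes(self, module: int) -> list[str]:
        return [g for g, m in self.module_of.items() if m == module]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "subtype_of": self.subtype_of,
                    "module_of": self.module_of,
                    "hazard_of": {str(k): v for k, v in self.hazard_of.items()},
                    "seed": self.seed,
                },
                indent=1,
            )
        )


def _split_sizes(total: int, parts: int) -> list[int]:
    base, extra = divmod(total, parts)
    return [base + (1 if i < extra else 0) for i in range(parts)]


def gen_network(
    m: int,
    n_modules: int,
    p_in: float = DEFAULT_P_IN,
    p_out: float = DEFAULT_P_OUT,
    seed: int = 0,
) -> tuple[GeneNetwork, SyntheticTruth]:
    """Planted-partition gene network with ``n_modules`` communities.

    Within-module edges appear with probability ``p_in`` and carry weights
    uniform(0.5, 1); between-module edges appear with probability ``p_out``
    and carry weights uniform(0, 0.5).  Genes are split near-equally across
    modules.
    """
    if not (0 <= p_out < p_in <= 1):
        raise ValueError("need 0 <= p_out < p_in <= 1")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(m)]
    module = np.repeat(np.arange(n_modules), _split_sizes(m, n_modules))

    same = module[:, None] == module[None, :]
    present = rng.random((m, m)) < np.where(same, p_in, p_out)
    weight = np.where(same, rng.uniform(0.5, 1.0, (m, m)), rng.uniform(0.0, 0.5, (m, m)))
    upper = np.triu(present & (weight > 0), 1)
    weights = np.where(upper, weight, 0.0)
    weights = weights + weights.T

    truth = SyntheticTruth(
        module_of={g: int(mod) for g, mod in zip(genes, module)}, seed=seed
    )
    return GeneNetwork(genes=genes, weights=weights), truth


def gen_cohort(
    network: GeneNetwork,
    truth: SyntheticTruth,
    n_samples: int,
    n_subtypes: int,
    driver_rate: float = DEFAULT_DRIVER_RATE,
    background_rate: float = DEFAULT_BACKGROUND_RATE,
    seed: int = 0,
    min_mutations: int = 6,
    passenger_bursts: int = 0,
    burst_rate: float | None = None,
) -> tuple[BinaryMutationMatrix, SyntheticTruth]:
    """Binary mutation cohort with subtype-specific community mutations.

    Each sample is assigned a subtype (near-equal split, shuffled); genes
    of the subtype's network module mutate independently at ``driver_rate``
    and all other genes at ``background_rate``.  Samples are resampled
    until they carry at least ``min_mutations`` mutated genes, so the
    full-exome outlier filter keeps the whole cohort.

    ``passenger_bursts`` emulates the structured component of passenger
    noise in real exomes: per sample, that many randomly chosen
    non-driver modules (modules beyond the first ``n_subtypes``, or any
    other module when none exist) additionally mutate at ``burst_rate``
    (default ``driver_rate``).  Unlike uniform background, such coherent
    passenger pathways create spurious network-smooth structure that
    obscures the subtype signal in exome-wide profiles while a
    driver-targeted panel excludes it.  Default 0 (off).
    """
    if not (0 <= background_rate < driver_rate < 1):
        raise ValueError("need 0 <= background_rate < driver_rate < 1")
    n_modules = len(set(truth.module_of.values()))
    if n_subtypes > n_modules:
        raise ValueError(f"{n_subtypes} subtypes need at least as many network modules")
    rng = np.random.default_rng(seed)
    genes = list(network.genes)
    module = np.array([truth.module_of[g] for g in genes])

    subtype = np.repeat(np.arange(n_subtypes), _split_sizes(n_samples, n_subtypes))
    rng.shuffle(subtype)
    samples = [f"S{j:04d}" for j in range(n_samples)]

    burst_rate = driver_rate if burst_rate is None else burst_rate
    passenger_pool = [mod for mod in range(n_modules) if mod >= n_subtypes]

    m = len(genes)
    values = np.zeros((m, n_samples), dtype=np.int8)
    for j in range(n_samples):
        rate = np.where(module == subtype[j], driver_rate, background_rate)
        if passenger_bursts:
            pool = passenger_pool or [mod for mod in range(n_modules) if mod != subtype[j]]
            hit = rng.choice(pool, size=min(passenger_bursts, len(pool)), replace=False)
            rate = np.where(np.isin(module, hit), np.maximum(rate, burst_rate), rate)
        for _ in range(1000):
            profile = (rng.random(m) < rate).astype(np.int8)
            if profile.sum() >= min_mutations:
                break
        else:  # pragma: no cover - rates pathologically low
            raise RuntimeError("could not draw a sample with enough mutations")
        values[:, j] = profile

    truth = SyntheticTruth(
        subtype_of={s: int(t) for s, t in zip(samples, subtype)},
        module_of=dict(truth.module_of),
        hazard_of=dict(truth.hazard_of),
        seed=truth.seed,
    )
    return BinaryMutationMatrix(values=values, genes=genes, samples=samples), truth


def gen_panel(
    truth: SyntheticTruth,
    coverage: float,
    decoys: int = 0,
    seed: int = 0,
    name: str = "synthetic-panel",
    modules: list[int] | None = None,
) -> GenePanel:
    """Driver-enriched gene panel.

    Samples ``floor(coverage * module size)`` genes from each covered
    module plus ``decoys`` random genes from outside the covered modules
    (background genes).  ``modules`` selects which communities the panel
    targets — real panels enrich known driver pathways, so pass the driver
    modules to emulate an informative panel over a passenger-laden exome;
    the default covers every module.
    """
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    rng = np.random.default_rng(seed)
    covered = sorted(set(truth.module_of.values())) if modules is None else sorted(modules)
    chosen: list[str] = []
    for mod in covered:
        members = sorted(g for g, m in truth.module_of.items() if m == mod)
        n_take = int(np.floor(coverage * len(members)))
        if n_take:
            chosen.extend(rng.choice(members, size=n_take, replace=False))
    pool = sorted(set(truth.module_of) - set(chosen))
    if decoys:
        chosen.extend(rng.choice(pool, size=min(decoys, len(pool)), replace=False))
    return GenePanel(name=name, genes=frozenset(chosen))


def gen_clinical(
    truth: SyntheticTruth,
    samples: list[str],
    baseline_hazard: float = 1.0 / 1000.0,
    hazard_ratios: dict[int, float] | None = None,
    censor_rate: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Exponential survival with subtype-proportional hazards.

    Event times are exponential with rate ``baseline_hazard * hr[subtype]``
    (days); censoring is an independent exponential calibrated so the
    expected censored fraction per subtype equals ``censor_rate``.  A
    binary tumor grade is attached: P(high grade) increases with the
    subtype's hazard, so grade associates with aggressive subtypes.
    """
    if baseline_hazard <= 0:
        raise ValueError("baseline hazard must be positive")
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    subtypes = sorted({truth.subtype_of[s] for s in samples})
    hazard_ratios = hazard_ratios or {t: 1.0 for t in subtypes}
    if any(hr <= 0 for hr in hazard_ratios.values()):
        raise ValueError("hazard ratios must be positive")
    rng = np.random.default_rng(seed)

    max_hr = max(hazard_ratios.values())
    rows = []
    for s in samples:
        t = truth.subtype_of[s]
        lam = baseline_hazard * hazard_ratios[t]
        event_time = rng.exponential(1.0 / lam)
        if censor_rate > 0:
            # P(censor before event) = mu / (lam + mu) = censor_rate
            mu = censor_rate / (1 - censor_rate) * lam
            censor_time = rng.exponential(1.0 / mu)
        else:
            censor_time = np.inf
        time = min(event_time, censor_time)
        p_high = hazard_ratios[t] / (max_hr + 1.0)
        rows.append(
            {
                "sample_id": s,
                "time": float(time),
                "event": int(event_time <= censor_time),
                "grade": "high" if rng.random() < p_high else "low",
            }
        )
    truth = SyntheticTruth(
        subtype_of=dict(truth.subtype_of),
        module_of=dict(truth.module_of),
        hazard_of={t: baseline_hazard * hazard_ratios[t] for t in subtypes},
        seed=truth.seed,
    )
    return pd.DataFrame(rows), truth


def cohort_to_mutation_table(
    matrix: BinaryMutationMatrix, seed: int = 0, silent_rate: float = 0.005
) -> pd.DataFrame:
    """Render a binary cohort as a MAF-like mutation table.

    Every mutated (gene, sample) cell becomes one missense record; a light
    sprinkling of silent records (``silent_rate`` per gene-sample pair) is
    added so parsing exercises the functional/non-functional split without
    changing the binarized matrix.
    """
    rng = np.random.default_rng(seed)
    rows = []
    ii, jj = np.nonzero(matrix.values)
    for i, j in zip(ii, jj):
        rows.append(
            {
                "Tumor_Sample_Barcode": matrix.samples[j],
                "Hugo_Symbol": matrix.genes[i],
                "Variant_Classification": "Missense_Mutation",
            }
        )
    silent = rng.random((matrix.n_genes, matrix.n_samples)) < silent_rate
    for i, j in zip(*np.nonzero(silent)):
        rows.append(
            {
                "Tumor_Sample_Barcode": matrix.samples[j],
                "Hugo_Symbol": matrix.genes[i],
                "Variant_Classification": "Silent",
            }
        )
    return pd.DataFrame(rows)


def write_simulation(
    outdir: str | Path,
    *,
    m: int = 200,
    n_modules: int = 4,
    n_samples: int = 120,
    n_subtypes: int = 4,
    p_in: float = DEFAULT_P_IN,
    p_out: float = DEFAULT_P_OUT,
    driver_rate: float = DEFAULT_DRIVER_RATE,
    background_rate: float = DEFAULT_BACKGROUND_RATE,
    panel_coverage: float = 0.8,
    panel_decoys: int = 10,
    hazard_ratios: dict[int, float] | None = None,
    censor_rate: float = 0.2,
    seed: int = 0,
) -> dict[str, Path]:
    """Simulate a full study and write mutations TSV, network TSV, panel
    TXT, clinical TSV and truth JSON into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net, truth = gen_network(m, n_modules, p_in, p_out, seed=seed)
    cohort, truth = gen_cohort(
        net, truth, n_samples, n_subtypes, driver_rate, background_rate, seed=seed + 1
    )
    panel = gen_panel(truth, panel_coverage, panel_decoys, seed=seed + 2)
    hazard_ratios = hazard_ratios or {t: float(2**t) for t in range(n_subtypes)}
    clinical, truth = gen_clinical(
        truth, cohort.samples, hazard_ratios=hazard_ratios,
        censor_rate=censor_rate, seed=seed + 3,
    )

    paths = {
        "mutations": outdir / "mutations.tsv",
        "network": outdir / "network.tsv",
        "panel": outdir / "panel.txt",
        "clinical": outdir / "clinical.tsv",
        "truth": outdir / "truth.json",
    }
    cohort_to_mutation_table(cohort, seed=seed + 4).to_csv(
        paths["mutations"], sep="\t", index=False
    )
    net.to_tsv(paths["network"])
    paths["panel"].write_text("\n".join(sorted(panel.genes)) + "\n")
    clinical.to_csv(paths["clinical"], sep="\t", index=False)
    truth.to_json(paths["truth"])
    return paths
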