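"""Genetic-algorithm-wrapped linear SVM feature selection.

A fixed-size subset of intensity features (default 50 of the 500 most
intense) is searched for by a simple wrapper GA: chromosomes are k-subsets
of feature indices, fitness is leave-one-out accuracy of a linear
soft-margin SVM (one-vs-rest, cost 100) classifying samples by strain, the
elite half survives each generation and offspring arise by uniform crossover
plus a single random gene replacement.  The selected features are the ones
that best discriminate the strains — the shortlist for structural follow-up.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "GASVMParams",
    "Chromosome",
    "loo_fitness",
    "ga_select",
    "synthetic_strain_panel",
]


@dataclass(frozen=True)
class GASVMParams:
    population_size: int = 25
    generations: int = 10
    mutation_rate: int = 1  # random gene replacements per offspring per generation
    svm_cost: float = 100.0
    class_weight_ratio: float = 1.0  # 1 -> balanced class weighting
    subset_size: int = 50
    n_input_features: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subset_size > self.n_input_features:
            raise ValueError("subset size exceeds the input feature count")
        if self.population_size < 2:
            raise ValueError("population must have at least two chromosomes")


@dataclass
class Chromosome:
    features: Tuple[int, ...]  # sorted, distinct feature indices
    fitness: float = float("nan")

    def __post_init__(self) -> None:
        if len(set(self.features)) != len(self.features):
            raise ValueError("chromosome indices must be distinct")
        self.features = tuple(sorted(self.features))


def _classifier(params: GASVMParams) -> SVC:
    # linear soft-margin SVM; multiclass by libsvm's pairwise voting, which is
    # far cheaper than one-vs-rest on these tiny near-duplicate-class panels
    class_weight = "balanced" if params.class_weight_ratio == 1.0 else None
    return SVC(kernel="linear", C=params.svm_cost, class_weight=class_weight)


def loo_fitness(
    X: np.ndarray,
    y: Sequence,
    subset: Sequence[int],
    params: GASVMParams | None = None,
) -> float:
    """Leave-one-out accuracy of the linear SVM on a feature subset.

    For each sample in turn, the classifier is trained on the remaining
    samples restricted to the subset columns (standardised on the training
    fold) and asked to label the held-out sample; the fitness is the
    fraction of correct labels.
    """
    params = params or GASVMParams()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] < 2:
        raise ValueError("leave-one-out needs at least two samples")
    if len(subset) == 0:
        raise ValueError("empty feature subset")
    cols = np.asarray(sorted(subset), dtype=int)
    Xs = X[:, cols]
    correct = 0
    for held in range(X.shape[0]):
        mask = np.ones(X.shape[0], dtype=bool)
        mask[held] = False
        if len(set(y[mask])) < 2:
            continue  # a fold with one class cannot be fit; counts as wrong
        scaler = StandardScaler().fit(Xs[mask])
        clf = _classifier(params)
        with warnings.catch_warnings():
            # many classes vs few samples is the normal regime here
            warnings.simplefilter("ignore", UserWarning)
            warnings.simplefilter("ignore", FutureWarning)
            clf.fit(scaler.transform(Xs[mask]), y[mask])
        if clf.predict(scaler.transform(Xs[held : held + 1]))[0] == y[held]:
            correct += 1
    return correct / X.shape[0]


def _random_subset(rng: np.random.Generator, params: GASVMParams) -> Tuple[int, ...]:
    return tuple(
        sorted(rng.choice(params.n_input_features, size=params.subset_size, replace=False))
    )


def _crossover(
    rng: np.random.Generator, a: Tuple[int, ...], b: Tuple[int, ...], k: int
) -> Tuple[Tuple[int, ...], Tuple[int, ...]]:
    """Uniform crossover producing two complementary k-subsets.

    Shared genes go to both children; the symmetric difference is split
    randomly in half between them, so every parental gene survives in
    exactly one child — crossover itself never discards an allele.
    """
    shared = sorted(set(a) & set(b))
    pool = sorted(set(a) ^ set(b))
    half = k - len(shared)
    picks = set(rng.choice(len(pool), size=half, replace=False).tolist())
    child1 = shared + [g for i, g in enumerate(pool) if i in picks]
    child2 = shared + [g for i, g in enumerate(pool) if i not in picks]
    return tuple(sorted(child1)), tuple(sorted(child2))


def _mutate(
    rng: np.random.Generator, chrom: Tuple[int, ...], n_swaps: int, n: int
) -> Tuple[int, ...]:
    genes = set(chrom)
    outside = np.array(sorted(set(range(n)) - genes))
    genes_list = sorted(genes)
    for _ in range(n_swaps):
        if len(outside) == 0:
            break
        out_idx = int(rng.integers(len(genes_list)))
        in_idx = int(rng.integers(len(outside)))
        removed = genes_list.pop(out_idx)
        genes_list.append(int(outside[in_idx]))
        outside[in_idx] = removed
        genes_list.sort()
    return tuple(genes_list)


def ga_select(
    X: np.ndarray,
    y: Sequence,
    params: GASVMParams | None = None,
) -> Tuple[Chromosome, List[dict]]:
    """Run the GA wrapper; returns the best-ever chromosome and a history.

    Each generation: evaluate leave-one-out fitness, keep the elite half
    (ties broken deterministically by chromosome content), refill the
    population by uniform crossover of random elite pairs, and apply
    ``mutation_rate`` random gene replacements to every offspring.  The
    best-ever fitness is nondecreasing across generations by elitism.
    Fully deterministic for a fixed seed.
    """
    params = params or GASVMParams()
    X = np.asarray(X, dtype=float)
    if X.shape[1] != params.n_input_features:
        raise ValueError(
            f"X has {X.shape[1]} features but params expect {params.n_input_features}"
        )
    rng = np.random.default_rng(params.seed)

    if params.subset_size == params.n_input_features:
        only = tuple(range(params.n_input_features))
        fitness = loo_fitness(X, y, only, params)
        chrom = Chromosome(only, fitness)
        return chrom, [{"generation": 0, "best": fitness, "mean": fitness,
                        "best_features": list(only)}]

    population = [_random_subset(rng, params) for _ in range(params.population_size)]
    cache: dict = {}

    def evaluate(subset: Tuple[int, ...]) -> float:
        if subset not in cache:
            cache[subset] = loo_fitness(X, y, subset, params)
        return cache[subset]

    best_ever: Chromosome | None = None
    history: List[dict] = []
    for generation in range(params.generations):
        scored = sorted(
            ((evaluate(c), c) for c in population), key=lambda fc: (-fc[0], fc[1])
        )
        top_fit, top_chrom = scored[0]
        if best_ever is None or top_fit > best_ever.fitness:
            best_ever = Chromosome(top_chrom, top_fit)
        history.append(
            {
                "generation": generation,
                "best": best_ever.fitness,
                "mean": float(np.mean([f for f, _ in scored])),
                "best_features": list(best_ever.features),
            }
        )
        elite = [c for _, c in scored[: max(2, params.population_size // 2)]]
        offspring = list(elite)
        # round-robin pairing over a shuffled elite: every elite chromosome
        # parents each generation, so (with complementary children) every
        # elite allele is transmitted to some offspring every generation
        order = list(rng.permutation(len(elite)))
        pair_idx = 0
        while len(offspring) < params.population_size:
            if pair_idx + 1 >= len(order):
                order = list(rng.permutation(len(elite)))
                pair_idx = 0
            a = elite[order[pair_idx]]
            b = elite[order[pair_idx + 1]]
            pair_idx += 2
            for child in _crossover(rng, a, b, params.subset_size):
                if len(offspring) >= params.population_size:
                    break
                child = _mutate(rng, child, params.mutation_rate,
                                params.n_input_features)
                offspring.append(child)
        population = offspring

    # final evaluation pass over the last population
    for chrom in population:
        fit = evaluate(chrom)
        if best_ever is None or fit > best_ever.fitness:
            best_ever = Chromosome(chrom, fit)
    assert best_ever is not None
    return best_ever, history


def synthetic_strain_panel(
    n_features: int = 500,
    n_informative: int = 5,
    n_other_strains: int = 3,
    n_replicates: int = 2,
    noise_sd: float = 0.0,
    effect: float = 3.0,
    seed: int = 0,
) -> Tuple[np.ndarray, List[str], List[int]]:
    """Synthetic log-intensity panel where selection has a known answer.

    Builds ``n_informative`` pairs of otherwise-identical strains: each pair
    shares a base profile and differs only in one informative feature
    (shifted by ``effect`` log units in the first member), so that feature is
    the sole evidence separating the pair.  ``n_other_strains`` further
    strains get distinct profiles and are separable from everything by many
    features.  Returns ``(X, labels, informative_indices)`` with
    ``n_replicates`` replicate rows per strain.

    By default replicates are exact technical duplicates (``noise_sd=0``):
    with i.i.d. replicate noise a wrapper search this aggressive can find
    noise columns whose frozen leave-one-out outcome resolves a pair by
    accident, which would blur what "recovering the planted features" means.
    With duplicates, a missing informative feature costs a fixed, provable
    accuracy deficit that no noise column can repay.
    """
    rng = np.random.default_rng(seed)
    informative = sorted(
        int(i) for i in rng.choice(n_features, size=n_informative, replace=False)
    )
    profiles: List[Tuple[str, np.ndarray]] = []
    for p in range(n_informative):
        base = rng.normal(0.0, 1.0, n_features)
        up = base.copy()
        up[informative[p]] += effect
        profiles.append((f"S{2 * p + 1:02d}", up))
        profiles.append((f"S{2 * p + 2:02d}", base))
    for q in range(n_other_strains):
        profiles.append(
            (f"S{2 * n_informative + q + 1:02d}", rng.normal(0.0, 1.0, n_features))
        )
    rows, labels = [], []
    for strain, profile in profiles:
        for _ in range(n_replicates):
            rows.append(profile + rng.normal(0.0, noise_sd, n_features))
            labels.append(strain)
    return np.array(rows), labels, informative
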