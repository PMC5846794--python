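"""Rank-based subject-signature classification and biomarker panel optimization.

The method, end to end:

1. A Wilcoxon rank-sum pre-filter keeps proteins whose two-sided p-value is at
   most ``filter_alpha`` in the training subjects.
2. Optionally, abundances are divided by each protein's mean over the training
   subjects to emphasise fold-changes (used for the long panel).
3. Each subject's retained proteins are ranked by descending abundance (ties
   broken by ascending protein id) and the subject's *signature* is the list
   of the first ``n1`` and the last ``n2`` proteins in that ranking.
4. Signatures are compared all-to-all with a distance built from a weighted
   Kolmogorov-Smirnov running-sum enrichment score: the protein at rank ``r``
   of a ranking of length ``P`` carries weight ``v_r = (P + 1 - r) ** w``; the
   running sum gains ``v_r / sum(hits)`` at a hit and loses ``1 / (P - |S|)``
   at a miss; the score is the running-sum value of largest magnitude, so it
   is +1 when the set sits exactly at the top of the ranking and -1 at the
   bottom.  The similarity of subjects A and B is

       s = [ES(topA|B) - ES(botA|B) + ES(topB|A) - ES(botB|A)] / 4

   and the distance is ``d = (1 - s) / 2``, which is symmetric, lies in
   [0, 1], and is 0 for a subject against itself.
5. A sample is assigned to the class (control / affected) whose training
   subjects have the smallest mean distance to it; an exact tie goes to
   control (deterministic and logged).
6. The biomarker panel is the union of the proteins appearing in at least one
   subject signature, aggregated over the cross-validation folds.
7. A genetic optimizer searches (n1, n2, filter_alpha) for either the
   shortest panel at maximal accuracy ("short" mode) or the longest panel at
   accuracy >= a floor ("long" mode).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io_formats import ExpressionDataset

logger = logging.getLogger("signet")


# ---------------------------------------------------------------------------
# Parameter and result types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SignatureParams:
    """Signature length (n1 top + n2 bottom), pre-filter stringency and weights."""

    n1: int
    n2: int
    filter_alpha: float = 0.05
    weight_exponent: float = 1.0
    foldchange_preprocess: bool = False

    def __post_init__(self) -> None:
        if self.n1 < 0 or self.n2 < 0 or self.n1 + self.n2 < 1:
            raise ValueError("need n1 >= 0, n2 >= 0 and n1 + n2 >= 1")
        if not (0.0 < self.filter_alpha <= 1.0):
            raise ValueError("filter_alpha must lie in (0, 1]")
        if self.weight_exponent < 0:
            raise ValueError("weight_exponent must be >= 0")


@dataclass(frozen=True)
class SubjectSignature:
    subject_id: str
    top: tuple[str, ...]
    bottom: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.top) & set(self.bottom):
            raise ValueError("top and bottom lists must be disjoint")

    @property
    def proteins(self) -> tuple[str, ...]:
        return self.top + self.bottom


@dataclass
class DistanceMatrix:
    subject_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.subject_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix must be square over subject_ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix must have zero diagonal")
        if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
            raise ValueError("distances must lie in [0, 1]")


@dataclass
class BiomarkerPanel:
    protein_ids: list[str]
    mode: str
    contributing: dict[str, set[str]]
    params: SignatureParams

    def __len__(self) -> int:
        return len(self.protein_ids)


@dataclass
class CVResult:
    k: int
    fold_accuracies: list[float]
    mean_accuracy: float
    predicted: dict[str, str]
    fold_assignment: dict[str, int]
    seed: int
    params: SignatureParams
    signatures: list[dict[str, SubjectSignature]] = field(default_factory=list)


@dataclass
class PermutationResult:
    B: int
    observed: float
    null_accuracies: np.ndarray
    p_value: float
    seed: int


@dataclass
class GAConfig:
    """Genetic-optimizer settings; hyperparameter defaults are method defaults,
    the search bounds and alpha grid are what the optimizer explores."""

    population_size: int = 40
    generations: int = 60
    tournament_size: int = 3
    crossover_rate: float = 0.8
    mutation_rate: float = 0.15
    n_min: int = 1
    n_max: int = 40
    alpha_grid: tuple[float, ...] = tuple(np.logspace(-12, np.log10(0.05), 12))
    mode: str = "short"
    accuracy_floor: float = 0.98
    seed: int = 0
    cv_folds: int = 5

    def __post_init__(self) -> None:
        for rate in (self.crossover_rate, self.mutation_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("GA rates must lie in [0, 1]")
        if self.n_min < 1 or self.n_max < self.n_min:
            raise ValueError("need 1 <= n_min <= n_max")
        if self.mode not in ("short", "long"):
            raise ValueError("mode must be 'short' or 'long'")


# ---------------------------------------------------------------------------
# Pre-filter and preprocessing
# ---------------------------------------------------------------------------


def wilcoxon_prefilter(dataset: ExpressionDataset, alpha: float) -> list[str]:
    """Retain proteins whose two-sided rank-sum p-value is <= alpha.

    The dataset should already be restricted to the training subjects; both
    classes must be present.  Retained proteins keep the input order.
    """
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must lie in (0, 1]")
    ctrl = dataset.values[dataset.class_mask("control")]
    aff = dataset.values[dataset.class_mask("affected")]
    if len(ctrl) == 0 or len(aff) == 0:
        raise ValueError("both classes must be present in the training subjects")
    pvals = _ranksum_pvalues(ctrl, aff)
    retained = [pid for pid, p in zip(dataset.protein_ids, pvals) if p <= alpha]
    if not retained:
        raise ValueError(
            f"no protein passed the Wilcoxon pre-filter at alpha={alpha!r}; "
            "use a larger alpha"
        )
    return retained


def _ranksum_pvalues(ctrl: np.ndarray, aff: np.ndarray) -> np.ndarray:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum p per column (exact for tiny
    tie-free samples, normal approximation with tie/continuity correction
    otherwise -- scipy's 'auto' policy)."""
    res = stats.mannwhitneyu(ctrl, aff, alternative="two-sided", axis=0, method="auto")
    return np.atleast_1d(res.pvalue)


def foldchange_preprocess(
    dataset: ExpressionDataset, means: np.ndarray | None = None
) -> tuple[ExpressionDataset, np.ndarray]:
    """Divide each protein's column by its mean over the dataset's subjects.

    Passing the ``means`` recorded from a training dataset applies the
    training normalisation to held-out subjects instead.  Returns the
    transformed dataset and the means used.
    """
    if means is None:
        means = dataset.values.mean(axis=0)
    means = np.asarray(means, dtype=float)
    out = replace(dataset, values=dataset.values / means[None, :])
    return out, means


# ---------------------------------------------------------------------------
# Signatures and the enrichment-score distance
# ---------------------------------------------------------------------------


def _ranking_order(values: np.ndarray, id_rank: np.ndarray) -> np.ndarray:
    """Indices sorting each row by descending value, ties by ascending id.

    ``values``: (n_subjects, P); ``id_rank``: (P,) position of each protein in
    ascending-id order.  Returns (n_subjects, P) of column indices.
    """
    return np.lexsort((np.broadcast_to(id_rank, values.shape), -values), axis=-1)


def make_signature(
    profile: Mapping[str, float] | Sequence[float],
    params: SignatureParams,
    protein_ids: Sequence[str] | None = None,
) -> SubjectSignature:
    """Build one subject's signature from its values over the retained proteins."""
    if isinstance(profile, Mapping):
        protein_ids = list(profile.keys())
        vals = np.array([profile[p] for p in protein_ids], dtype=float)
    else:
        if protein_ids is None:
            raise ValueError("protein_ids required when profile is a plain sequence")
        vals = np.asarray(profile, dtype=float)
    P = len(protein_ids)
    if params.n1 + params.n2 > P:
        raise ValueError(f"n1 + n2 = {params.n1 + params.n2} exceeds {P} retained proteins")
    id_rank = np.empty(P, dtype=int)
    id_rank[np.argsort(np.asarray(protein_ids, dtype=object))] = np.arange(P)
    order = _ranking_order(vals[None, :], id_rank)[0]
    ranked = [protein_ids[j] for j in order]
    return SubjectSignature(
        subject_id="",
        top=tuple(ranked[: params.n1]),
        bottom=tuple(ranked[P - params.n2 :]) if params.n2 else (),
    )


def _es_from_ranks(ranks: np.ndarray, P: int, w: float) -> np.ndarray:
    """Weighted KS running-sum enrichment score from 1-based hit ranks.

    ``ranks``: (..., k) distinct ranks of the set members in a ranking of
    length P.  Vectorised over leading axes.  The extrema of the running sum
    occur immediately after each hit and immediately before each hit, so only
    2k candidate values need to be examined.
    """
    ranks = np.asarray(ranks, dtype=float)
    k = ranks.shape[-1]
    if k == 0:
        raise ValueError("enrichment score of an empty set is undefined")
    if k >= P:
        raise ValueError("gene set must be a strict subset of the ranking")
    r = np.sort(ranks, axis=-1)
    v = (P + 1.0 - r) ** w
    V = v.sum(axis=-1, keepdims=True)
    cums = np.cumsum(v, axis=-1)
    j = np.arange(1, k + 1, dtype=float)
    after = cums / V - (r - j) / (P - k)
    before = after - v / V
    cand = np.concatenate([after, before], axis=-1)
    mx = cand.max(axis=-1)
    mn = cand.min(axis=-1)
    return np.where(mx >= -mn, mx, mn)


def enrichment_score(
    gene_set: Iterable[str], ranking: Sequence[str], w: float = 1.0
) -> float:
    """Weighted enrichment score of a protein set against a full ranking.

    +1 when the set occupies exactly the top of the ranking, -1 at the bottom.
    """
    ranking = list(ranking)
    members = list(dict.fromkeys(gene_set))
    if not members:
        raise ValueError("gene set is empty")
    pos = {pid: i + 1 for i, pid in enumerate(ranking)}
    missing = [m for m in members if m not in pos]
    if missing:
        raise ValueError(f"set members absent from ranking: {missing[:5]}")
    if len(members) >= len(ranking):
        raise ValueError("gene set must be a strict subset of the ranking")
    ranks = np.array([[pos[m] for m in members]], dtype=float)
    return float(_es_from_ranks(ranks, len(ranking), w)[0])


def signature_distance(
    sig_a: SubjectSignature,
    ranking_a: Sequence[str],
    sig_b: SubjectSignature,
    ranking_b: Sequence[str],
    w: float = 1.0,
) -> float:
    """Symmetrized enrichment-score distance between two subject signatures."""
    if set(ranking_a) != set(ranking_b):
        raise ValueError("signatures were built over different protein universes")
    terms: list[float] = []
    if sig_a.top or sig_b.top:
        if not (sig_a.top and sig_b.top):
            raise ValueError("signatures have inconsistent top lengths")
        terms += [enrichment_score(sig_a.top, ranking_b, w), enrichment_score(sig_b.top, ranking_a, w)]
    if sig_a.bottom or sig_b.bottom:
        if not (sig_a.bottom and sig_b.bottom):
            raise ValueError("signatures have inconsistent bottom lengths")
        terms += [-enrichment_score(sig_a.bottom, ranking_b, w), -enrichment_score(sig_b.bottom, ranking_a, w)]
    s = float(np.mean(terms))
    return (1.0 - s) / 2.0


def distance_matrix(
    signatures: Sequence[SubjectSignature],
    rankings: Sequence[Sequence[str]],
    w: float = 1.0,
) -> DistanceMatrix:
    """All-to-all signature distances (symmetric, zero diagonal, in [0, 1])."""
    n = len(signatures)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if len(rankings) != n:
        raise ValueError("one ranking per signature required")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = signature_distance(
                signatures[i], rankings[i], signatures[j], rankings[j], w
            )
    ids = [s.subject_id or f"subject_{i}" for i, s in enumerate(signatures)]
    return DistanceMatrix(subject_ids=ids, values=d)


def classify_subject(
    distances: Mapping[str, float] | np.ndarray,
    training_labels: Sequence[str],
) -> str:
    """Label with the smaller mean distance; an exact tie goes to control."""
    if isinstance(distances, Mapping):
        d = np.array(list(distances.values()), dtype=float)
    else:
        d = np.asarray(distances, dtype=float)
    labels = np.asarray(training_labels, dtype=object)
    if d.shape != labels.shape:
        raise ValueError("one distance per training subject required")
    masks = {lab: labels == lab for lab in ("control", "affected")}
    if not masks["control"].any() or not masks["affected"].any():
        raise ValueError("both classes must be present in the training set")
    mean_c = d[masks["control"]].mean()
    mean_a = d[masks["affected"]].mean()
    if mean_c == mean_a:
        logger.warning("mean-distance tie; assigning 'control'")
        return "control"
    return "control" if mean_c < mean_a else "affected"


# ---------------------------------------------------------------------------
# Cross-validation engine
# ---------------------------------------------------------------------------


class _CVEngine:
    """Caches fold splits, per-fold pre-filter p-values, and per-(fold, alpha)
    rankings so that the genetic optimizer can evaluate many (n1, n2, alpha)
    chromosomes against identical folds cheaply."""

    def __init__(self, dataset: ExpressionDataset, k: int, seed: int) -> None:
        labels = dataset.class_labels
        for lab in ("control", "affected"):
            if (labels == lab).sum() < k:
                raise ValueError(f"class {lab!r} has fewer than k={k} members")
        self.dataset = dataset
        self.k = k
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.fold_of = np.empty(dataset.n_subjects, dtype=int)
        for lab in ("control", "affected"):
            idx = np.flatnonzero(labels == lab)
            rng.shuffle(idx)
            for f, chunk in enumerate(np.array_split(idx, k)):
                self.fold_of[chunk] = f
        ids = np.asarray(dataset.protein_ids, dtype=object)
        self.id_rank = np.empty(len(ids), dtype=int)
        self.id_rank[np.argsort(ids)] = np.arange(len(ids))
        self._fold_pvals: dict[int, np.ndarray] = {}
        self._fold_data: dict[tuple[int, float, bool], tuple] = {}

    def _pvals(self, fold: int) -> np.ndarray:
        if fold not in self._fold_pvals:
            train = self.fold_of != fold
            labels = self.dataset.class_labels
            ctrl = self.dataset.values[train & (labels == "control")]
            aff = self.dataset.values[train & (labels == "affected")]
            self._fold_pvals[fold] = _ranksum_pvalues(ctrl, aff)
        return self._fold_pvals[fold]

    def _fold_arrays(self, fold: int, alpha: float, fc: bool):
        key = (fold, alpha, fc)
        if key not in self._fold_data:
            retained = np.flatnonzero(self._pvals(fold) <= alpha)
            if retained.size == 0:
                raise ValueError(
                    f"no protein passed the Wilcoxon pre-filter at alpha={alpha!r}; "
                    "use a larger alpha"
                )
            X = self.dataset.values[:, retained]
            if fc:
                train = self.fold_of != fold
                means = X[train].mean(axis=0)
                X = X / means[None, :]
            order = _ranking_order(X, self.id_rank[retained])
            pos = np.empty_like(order)
            rows = np.arange(order.shape[0])[:, None]
            pos[rows, order] = np.arange(1, order.shape[1] + 1)
            self._fold_data[key] = (retained, order, pos)
        return self._fold_data[key]

    def evaluate(self, params: SignatureParams, build_objects: bool = False) -> CVResult:
        ds = self.dataset
        n1, n2, w = params.n1, params.n2, params.weight_exponent
        labels = ds.class_labels
        fold_acc: list[float] = []
        predicted: dict[str, str] = {}
        panel_idx: set[int] = set()
        all_sigs: list[dict[str, SubjectSignature]] = []
        for fold in range(self.k):
            retained, order, pos = self._fold_arrays(fold, params.filter_alpha, params.foldchange_preprocess)
            P = retained.size
            if n1 + n2 > P:
                raise ValueError(f"n1 + n2 = {n1 + n2} exceeds {P} retained proteins (fold {fold})")
            test = np.flatnonzero(self.fold_of == fold)
            train = np.flatnonzero(self.fold_of != fold)
            top = order[:, :n1]
            bot = order[:, P - n2 :] if n2 else np.empty((order.shape[0], 0), dtype=int)
            panel_idx.update(retained[np.unique(top)])
            if n2:
                panel_idx.update(retained[np.unique(bot)])

            terms = np.zeros((train.size, test.size))
            n_terms = 0
            if n1:
                terms += _es_from_ranks(pos[train][:, top[test]], P, w)
                terms += _es_from_ranks(pos[test][:, top[train]], P, w).T
                n_terms += 2
            if n2:
                terms -= _es_from_ranks(pos[train][:, bot[test]], P, w)
                terms -= _es_from_ranks(pos[test][:, bot[train]], P, w).T
                n_terms += 2
            s = terms / n_terms
            d = (1.0 - s) / 2.0  # (train, test)

            is_ctrl = labels[train] == "control"
            mean_c = d[is_ctrl].mean(axis=0)
            mean_a = d[~is_ctrl].mean(axis=0)
            pred = np.where(mean_c <= mean_a, "control", "affected")
            n_ties = int((mean_c == mean_a).sum())
            if n_ties:
                logger.warning("%d mean-distance tie(s) in fold %d assigned 'control'", n_ties, fold)
            for t, lab in zip(test, pred):
                predicted[ds.subject_ids[t]] = str(lab)
            fold_acc.append(float((pred == labels[test]).mean()))

            if build_objects:
                ids = np.asarray(ds.protein_ids, dtype=object)
                sigs: dict[str, SubjectSignature] = {}
                for s_i in range(ds.n_subjects):
                    sigs[ds.subject_ids[s_i]] = SubjectSignature(
                        subject_id=ds.subject_ids[s_i],
                        top=tuple(ids[retained[top[s_i]]]),
                        bottom=tuple(ids[retained[bot[s_i]]]) if n2 else (),
                    )
                all_sigs.append(sigs)

        result = CVResult(
            k=self.k,
            fold_accuracies=fold_acc,
            mean_accuracy=float(np.mean(fold_acc)),
            predicted=predicted,
            fold_assignment={ds.subject_ids[i]: int(f) for i, f in enumerate(self.fold_of)},
            seed=self.seed,
            params=params,
            signatures=all_sigs,
        )
        result.panel_protein_ids = sorted(  # type: ignore[attr-defined]
            np.asarray(ds.protein_ids, dtype=object)[sorted(panel_idx)]
        )
        return result


def cross_validate(
    dataset: ExpressionDataset,
    params: SignatureParams,
    k: int = 5,
    seed: int = 0,
    build_objects: bool = True,
) -> CVResult:
    """Stratified k-fold cross-validation of the signature classifier.

    Per fold, the pre-filter and (optional) fold-change preprocessing are
    fitted on the training subjects only; held-out subjects are ranked over
    the training fold's retained proteins using the training statistics, then
    classified against the training signatures.
    """
    return _CVEngine(dataset, k, seed).evaluate(params, build_objects=build_objects)


def aggregate_panel(
    signatures: Iterable[Mapping[str, SubjectSignature]] | Iterable[SubjectSignature],
    mode: str,
    params: SignatureParams,
) -> BiomarkerPanel:
    """Union of the proteins appearing in at least one subject signature."""
    flat: list[SubjectSignature] = []
    for item in signatures:
        if isinstance(item, SubjectSignature):
            flat.append(item)
        else:
            flat.extend(item.values())
    if not flat:
        raise ValueError("no signatures to aggregate")
    contributing: dict[str, set[str]] = {}
    for sig in flat:
        for pid in sig.proteins:
            contributing.setdefault(pid, set()).add(sig.subject_id)
    return BiomarkerPanel(
        protein_ids=sorted(contributing),
        mode=mode,
        contributing=contributing,
        params=params,
    )


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------


def permutation_test(
    dataset: ExpressionDataset,
    params: SignatureParams,
    k: int = 5,
    B: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Empirical significance of the observed mean CV accuracy.

    Class labels are shuffled B times; the full cross-validation (pre-filter
    included) is re-run on each shuffled cohort.  p = (#{null >= obs} + 1) /
    (B + 1).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    observed = _CVEngine(dataset, k, seed).evaluate(params).mean_accuracy
    null = np.empty(B)
    filled = 0
    attempts = 0
    max_attempts = 20 * B
    n_skipped = 0
    while filled < B:
        if attempts >= max_attempts:
            raise ValueError(
                "the pre-filter leaves fewer than n1 + n2 proteins under almost "
                f"all label permutations at alpha={params.filter_alpha!r}; the "
                "permutation null is undefined at these parameters"
            )
        attempts += 1
        perm = replace(dataset, class_labels=rng.permutation(dataset.class_labels))
        cv_seed = int(rng.integers(2**31 - 1))
        try:
            null[filled] = _CVEngine(perm, k, cv_seed).evaluate(params).mean_accuracy
        except ValueError:
            # under a shuffled cohort the pre-filter can retain fewer than
            # n1 + n2 proteins; the accuracy statistic is undefined for such a
            # permutation, so it is redrawn (logged)
            n_skipped += 1
            continue
        filled += 1
    if n_skipped:
        logger.info(
            "%d permutation(s) redrawn because the pre-filter left fewer than "
            "n1 + n2 proteins",
            n_skipped,
        )
    p = (float((null >= observed).sum()) + 1.0) / (B + 1.0)
    return PermutationResult(B=B, observed=observed, null_accuracies=null, p_value=p, seed=seed)


# ---------------------------------------------------------------------------
# Genetic optimizer
# ---------------------------------------------------------------------------


def optimize_parameters(
    dataset: ExpressionDataset, ga: GAConfig
) -> tuple[SignatureParams, BiomarkerPanel, CVResult]:
    """Genetic search over (n1, n2, filter_alpha) for the short or long panel.

    Short mode maximizes (mean CV accuracy, -panel size) lexicographically;
    long mode maximizes panel size among chromosomes whose accuracy is at
    least ``accuracy_floor``.  Elitism keeps the best chromosome; the search
    is deterministic under ``ga.seed``.
    """
    rng = np.random.default_rng(ga.seed)
    engine = _CVEngine(dataset, ga.cv_folds, ga.seed)
    n_alpha = len(ga.alpha_grid)
    cache: dict[tuple[int, int, int], tuple] = {}

    def params_of(chrom: tuple[int, int, int]) -> SignatureParams:
        return SignatureParams(
            n1=chrom[0],
            n2=chrom[1],
            filter_alpha=float(ga.alpha_grid[chrom[2]]),
            foldchange_preprocess=(ga.mode == "long"),
        )

    def fitness(chrom: tuple[int, int, int]) -> tuple:
        if chrom not in cache:
            try:
                cv = engine.evaluate(params_of(chrom))
                size = len(cv.panel_protein_ids)  # type: ignore[attr-defined]
                acc = cv.mean_accuracy
                if ga.mode == "short":
                    fit = (0, acc, -size)
                else:
                    fit = (1, size, acc) if acc >= ga.accuracy_floor else (0, acc, 0)
            except ValueError:
                fit = (-1, 0.0, 0)
                acc = np.nan
            cache[chrom] = (fit, acc)
        return cache[chrom][0]

    def random_chrom() -> tuple[int, int, int]:
        return (
            int(rng.integers(ga.n_min, ga.n_max + 1)),
            int(rng.integers(ga.n_min, ga.n_max + 1)),
            int(rng.integers(n_alpha)),
        )

    def mutate(chrom: tuple[int, int, int]) -> tuple[int, int, int]:
        genes = list(chrom)
        for g in range(3):
            if rng.random() < ga.mutation_rate:
                if g < 2:
                    genes[g] = int(rng.integers(ga.n_min, ga.n_max + 1))
                else:
                    genes[g] = int(rng.integers(n_alpha))
        return tuple(genes)  # type: ignore[return-value]

    # seed the population with the smallest signature at every pre-filter
    # stringency so the feasible region is covered from generation zero,
    # then fill with random chromosomes
    pop = [(ga.n_min, ga.n_min, i) for i in range(min(n_alpha, ga.population_size))]
    pop += [random_chrom() for _ in range(ga.population_size - len(pop))]
    best = max(pop, key=fitness)
    for _ in range(ga.generations):
        nxt = [best]  # elitism
        while len(nxt) < ga.population_size:
            contenders = [pop[int(rng.integers(len(pop)))] for _ in range(ga.tournament_size)]
            p1 = max(contenders, key=fitness)
            contenders = [pop[int(rng.integers(len(pop)))] for _ in range(ga.tournament_size)]
            p2 = max(contenders, key=fitness)
            if rng.random() < ga.crossover_rate:
                child = tuple(p1[g] if rng.random() < 0.5 else p2[g] for g in range(3))
            else:
                child = p1
            nxt.append(mutate(child))  # type: ignore[arg-type]
        pop = nxt
        best = max(pop + [best], key=fitness)

    best_fit = fitness(best)
    if best_fit[0] < 0:
        raise ValueError("no valid chromosome found; widen the search bounds")
    if ga.mode == "long" and best_fit[0] < 1:
        raise ValueError(
            "no parameter setting reached the long-mode accuracy floor "
            f"{ga.accuracy_floor}; best accuracy found: {cache[best][1]:.4f}"
        )
    params = params_of(best)
    cv = engine.evaluate(params, build_objects=True)
    panel = aggregate_panel(cv.signatures, ga.mode, params)
    return params, panel, cv


# ---------------------------------------------------------------------------
# Convenience: full-cohort distance matrix
# ---------------------------------------------------------------------------


def compute_distance_matrix(
    dataset: ExpressionDataset, params: SignatureParams
) -> DistanceMatrix:
    """Pre-filter on the full cohort, build all signatures and rankings, and
    return the all-to-all distance matrix (the subject-map input)."""
    retained = wilcoxon_prefilter(dataset, params.filter_alpha)
    ds = dataset
    if params.foldchange_preprocess:
        ds, _ = foldchange_preprocess(dataset)
    col = {p: i for i, p in enumerate(ds.protein_ids)}
    idx = [col[p] for p in retained]
    X = ds.values[:, idx]
    ids = np.asarray(retained, dtype=object)
    id_rank = np.empty(len(ids), dtype=int)
    id_rank[np.argsort(ids)] = np.arange(len(ids))
    order = _ranking_order(X, id_rank)
    P = len(retained)
    if params.n1 + params.n2 > P:
        raise ValueError(f"n1 + n2 exceeds {P} retained proteins")
    sigs, rankings = [], []
    for i, sid in enumerate(ds.subject_ids):
        ranked = list(ids[order[i]])
        sigs.append(
            SubjectSignature(
                subject_id=sid,
                top=tuple(ranked[: params.n1]),
                bottom=tuple(ranked[P - params.n2 :]) if params.n2 else (),
            )
        )
        rankings.append(ranked)
    return distance_matrix(sigs, rankings, params.weight_exponent)
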