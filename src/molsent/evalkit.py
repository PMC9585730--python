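"""Metrics, dataset splits, and diagnostics for QSAR model evaluation.

The ROC-AUC is computed from the rank-sum statistic

    AUC = (1 / (M N)) * [ sum_{i in positive} rank_i  -  M (1 + M) / 2 ]

where ranks are ascending-score ranks with mid-ranks for ties and M, N are
the positive and negative counts — the Mann-Whitney form, equal to the
probability that a random positive outscores a random negative (ties count
half).

R-squared follows the printed convention of this pipeline: the total sum of
squares is centered on the mean of the *predictions*,

    R^2 = 1 - RSS / TSS,   TSS = sum_i (y_bar - t_i)^2 ,

with the conventional target-mean variant available behind
``center="targets"``.  Q^2 = 1 - PRESS / TSS measures goodness of prediction
on held-out data against a reference TSS.

Splits: seeded random 8:1:1 partition, and a Bemis-Murcko scaffold split that
groups molecules by their ring-system framework and assigns whole groups
(largest first) to train, then validation, then test, so no scaffold spans
two subsets whenever group sizes permit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as _scipy_stats

from .graph import generate_sentence, mol_from_smiles


@dataclass
class SplitIndices:
    train: list[int]
    validation: list[int]
    test: list[int]

    def __post_init__(self):
        all_idx = self.train + self.validation + self.test
        if len(set(all_idx)) != len(all_idx):
            raise ValueError("split subsets must be pairwise disjoint")


# ---------------------------------------------------------------------------
# metrics

def auc(scores, labels) -> float:
    """Rank-statistic ROC-AUC with mid-rank tie handling."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length vectors")
    if not np.all(np.isin(labels, (0, 1))):
        raise ValueError("labels must be binary")
    m = int(labels.sum())
    n = len(labels) - m
    if m == 0 or n == 0:
        raise ValueError("AUC requires at least one positive and one negative")
    ranks = _scipy_stats.rankdata(scores, method="average")
    return float((ranks[labels == 1].sum() - m * (1 + m) / 2) / (m * n))


def rmse(predictions, targets) -> float:
    """Root mean squared error."""
    y = np.asarray(predictions, dtype=np.float64)
    t = np.asarray(targets, dtype=np.float64)
    if y.size == 0 or y.shape != t.shape:
        raise ValueError("predictions and targets must be equal-length and nonempty")
    return float(np.sqrt(np.mean((y - t) ** 2)))


def r_squared(predictions, targets, center: str = "predictions") -> float:
    """R^2 = 1 - RSS/TSS with TSS centered on the prediction mean.

    ``center="targets"`` selects the conventional variant centered on the
    target mean instead.
    """
    y = np.asarray(predictions, dtype=np.float64)
    t = np.asarray(targets, dtype=np.float64)
    if y.size == 0 or y.shape != t.shape:
        raise ValueError("predictions and targets must be equal-length and nonempty")
    if center not in ("predictions", "targets"):
        raise ValueError("center must be 'predictions' or 'targets'")
    rss = float(np.sum((y - t) ** 2))
    bar = y.mean() if center == "predictions" else t.mean()
    tss = float(np.sum((bar - t) ** 2))
    if tss == 0.0:
        raise ZeroDivisionError("TSS is zero; R^2 undefined for these inputs")
    return 1.0 - rss / tss


def q_squared(predictions, targets, training_tss_reference: float) -> float:
    """Q^2 = 1 - PRESS/TSS on held-out data, against a reference TSS."""
    y = np.asarray(predictions, dtype=np.float64)
    t = np.asarray(targets, dtype=np.float64)
    if y.size == 0 or y.shape != t.shape:
        raise ValueError("predictions and targets must be equal-length and nonempty")
    if training_tss_reference == 0.0:
        raise ZeroDivisionError("reference TSS is zero; Q^2 undefined")
    press = float(np.sum((y - t) ** 2))
    return 1.0 - press / float(training_tss_reference)


def positive_ratio(labels) -> float:
    """Fraction of positive labels in a binary label vector."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty labels")
    if not np.all(np.isin(labels, (0, 1))):
        raise ValueError("labels must be binary")
    return float(labels.mean())


def paired_t_test(metric_runs_a, metric_runs_b) -> float:
    """Two-sided paired t-test p-value between matched metric runs."""
    a = np.asarray(metric_runs_a, dtype=np.float64)
    b = np.asarray(metric_runs_b, dtype=np.float64)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length runs of >= 2 values")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        raise ValueError("paired t-test undefined: differences have zero variance")
    return float(_scipy_stats.ttest_rel(a, b).pvalue)


# ---------------------------------------------------------------------------
# splits

def random_split(n: int, ratios=(0.8, 0.1, 0.1), seed: int = 0) -> SplitIndices:
    """Seeded shuffle partitioned at floor(r1*n) and floor((r1+r2)*n)."""
    if n < 3:
        raise ValueError("need at least 3 samples for a 3-way split")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    perm = np.random.default_rng(seed).permutation(n)
    a = int(np.floor(ratios[0] * n))
    b = int(np.floor((ratios[0] + ratios[1]) * n))
    return SplitIndices(
        train=perm[:a].tolist(),
        validation=perm[a:b].tolist(),
        test=perm[b:].tolist(),
    )


def murcko_scaffold(smiles: str) -> str:
    """Bemis-Murcko scaffold SMILES ('' for acyclic molecules)."""
    from rdkit.Chem.Scaffolds import MurckoScaffold
    from rdkit import Chem

    mol = mol_from_smiles(smiles)
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    return Chem.MolToSmiles(scaffold)


def scaffold_split(
    smiles_list: list[str], ratios=(0.8, 0.1, 0.1), seed: int = 0
) -> SplitIndices:
    """Group molecules by Bemis-Murcko scaffold and fill train, then
    validation, then test with whole groups, largest group first.

    A group larger than the remaining train quota still goes to train (the
    overflow-to-train rule), so validation/test never receive a partial
    scaffold.  Ties in group size are broken by scaffold string, then the
    seeded shuffle order, making the split deterministic.
    """
    bad = []
    scaffolds = []
    for s in smiles_list:
        try:
            scaffolds.append(murcko_scaffold(s))
        except Exception:
            bad.append(s)
    if bad:
        raise ValueError(f"unparseable SMILES in scaffold split: {bad}")
    groups: dict[str, list[int]] = {}
    for i, scaf in enumerate(scaffolds):
        groups.setdefault(scaf, []).append(i)
    n = len(smiles_list)
    rng = np.random.default_rng(seed)
    keys = list(groups)
    rng.shuffle(keys)
    keys.sort(key=lambda k: (-len(groups[k]), k))
    quota_train = ratios[0] * n
    quota_val = ratios[1] * n
    train: list[int] = []
    val: list[int] = []
    test: list[int] = []
    for key in keys:
        members = groups[key]
        if len(train) < quota_train:
            train.extend(members)
        elif len(val) + len(members) <= quota_val or not val:
            val.extend(members)
        else:
            test.extend(members)
    if not val or not test:
        warnings.warn(
            "scaffold split produced an empty validation or test subset "
            "(too few scaffold groups)",
            stacklevel=2,
        )
    return SplitIndices(train=train, validation=val, test=test)


# ---------------------------------------------------------------------------
# dataset diagnostics

def _identifier_set(smiles: str, max_radius: int = 1) -> frozenset[int]:
    return frozenset(generate_sentence(smiles, max_radius).tokens)


def tanimoto(a: frozenset, b: frozenset) -> float:
    """Intersection-over-union of two fingerprint sets."""
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def mean_cross_similarity(
    train_smiles: list[str], test_smiles: list[str], max_radius: int = 1
) -> dict:
    """Average Tanimoto similarity of each training molecule to the test set.

    Similarity uses the molecules' radius<=``max_radius`` substructure
    identifier sets.  Returns per-train-molecule means plus summary
    statistics (max, median, mean).
    """
    if not train_smiles or not test_smiles:
        raise ValueError("train and test sets must be nonempty")
    test_sets = [_identifier_set(s, max_radius) for s in test_smiles]
    per_train = []
    for s in train_smiles:
        fp = _identifier_set(s, max_radius)
        per_train.append(float(np.mean([tanimoto(fp, t) for t in test_sets])))
    arr = np.asarray(per_train)
    return {
        "per_train_mean_similarity": per_train,
        "max": float(arr.max()),
        "median": float(np.median(arr)),
        "mean": float(arr.mean()),
    }
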