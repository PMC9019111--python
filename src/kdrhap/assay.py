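"""Surveillance SNP panel design: information-gain ranking of SNPs and
decision trees that classify a haplotype into its resistance group.

The practical question is how few SNP assays a surveillance lab needs in
order to tell not just whether a mosquito carries a resistance allele,
but which haplotype group (i.e. which resistance outbreak) it belongs
to.  SNPs are ranked by the entropy reduction they give on the group
label; greedy decision trees (information-gain splits, the ID3 scheme, or
Gini splits as in CART) are then grown over binary SNP features and
scored by stratified k-fold cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .hapmatrix import HaplotypeMatrix

__all__ = [
    "information_gain",
    "entropy_bits",
    "DecisionTree",
    "build_tree",
    "stratified_cv_accuracy",
    "panel_frequency_table",
    "LabelledFeatureMatrix",
]


# ------------------------------------------------------------- entropy


def entropy_bits(labels: np.ndarray) -> float:
    """Shannon entropy of a label vector, in bits."""
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def information_gain(feature: np.ndarray, labels: np.ndarray) -> float:
    """IG = H(labels) - sum_v (n_v/n) H(labels | feature = v), in bits."""
    feature = np.asarray(feature)
    labels = np.asarray(labels)
    if feature.shape != labels.shape:
        raise ValueError("feature and labels differ in length")
    n = labels.size
    total = entropy_bits(labels)
    cond = 0.0
    for v in np.unique(feature):
        sel = feature == v
        cond += sel.sum() / n * entropy_bits(labels[sel])
    return max(total - cond, 0.0)


def _gini(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(1.0 - (p**2).sum())


def _split_gain(feature: np.ndarray, labels: np.ndarray, criterion: str) -> float:
    if criterion == "information_gain":
        return information_gain(feature, labels)
    if criterion != "gini":
        raise ValueError(f"unknown criterion {criterion!r}")
    n = labels.size
    impurity = _gini(labels)
    cond = 0.0
    for v in np.unique(feature):
        sel = feature == v
        cond += sel.sum() / n * _gini(labels[sel])
    return max(impurity - cond, 0.0)


# ------------------------------------------------------------------ data


@dataclass
class LabelledFeatureMatrix:
    """Haplotypes x binary SNP features with a group label per haplotype."""

    features: np.ndarray  # (n_haplotypes, n_snps), values in {0, 1}
    labels: np.ndarray
    snp_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.int8)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D")
        if self.features.shape[0] != self.labels.size:
            raise ValueError("feature rows and labels differ in length")
        if not np.isin(self.features, (0, 1)).all():
            raise ValueError("features must be binary")
        if not self.snp_names:
            self.snp_names = [f"snp{i}" for i in range(self.features.shape[1])]

    @classmethod
    def from_haplotypes(
        cls,
        haps: HaplotypeMatrix,
        assignment: list[str],
        region: tuple[int, int] | None = None,
        merge_to_wildtype: tuple[str, ...] = ("wt",),
    ) -> "LabelledFeatureMatrix":
        """Binary carrier features from the biallelic sites of a region.

        All labels in ``merge_to_wildtype`` collapse into a single ``wt``
        class, matching the surveillance framing where only resistance
        backgrounds need distinguishing from each other.
        """
        rows = (
            np.arange(haps.n_sites) if region is None else haps.site_index_in(*region)
        )
        mask = haps.biallelic_mask()
        rows = rows[mask[rows]]
        features = (haps.codes[rows].T > 0).astype(np.int8)
        labels = np.array(
            ["wt" if lab in merge_to_wildtype else lab for lab in assignment]
        )
        names = [f"{haps.sites[r].chrom}:{haps.sites[r].pos}" for r in rows]
        return cls(features=features, labels=labels, snp_names=names)


# ------------------------------------------------------------------ tree


@dataclass
class _Node:
    feature: int | None = None  # None at leaves
    prediction: object = None
    children: dict[int, "_Node"] = field(default_factory=dict)


@dataclass
class DecisionTree:
    """Greedy top-down decision tree over binary SNP features.

    Splits maximise the criterion gain; ties are broken by the lowest SNP
    index (then by a seeded order if ``stochastic_ties``), leaves predict
    the majority class (ties to the lexicographically lowest label), and
    growth stops on purity, max depth, or no positive gain — except that a
    zero-gain split is still taken when a one-step lookahead finds a
    positive-gain split in a child, so parity patterns (XOR-style allele
    combinations) remain learnable.
    """

    criterion: str
    max_depth: int
    root: _Node = field(default=None, repr=False)
    snp_names: list[str] = field(default_factory=list)

    def predict(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features))
        out = []
        for row in features:
            node = self.root
            while node.feature is not None:
                node = node.children[int(row[node.feature])]
            out.append(node.prediction)
        return np.array(out)

    def used_features(self) -> set[int]:
        used: set[int] = set()
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.feature is not None:
                used.add(node.feature)
                stack.extend(node.children.values())
        return used

    def depth(self) -> int:
        def _d(node: _Node) -> int:
            if node.feature is None:
                return 0
            return 1 + max(_d(c) for c in node.children.values())

        return _d(self.root)

    def to_text(self) -> str:
        lines: list[str] = []

        def _walk(node: _Node, indent: int, prefix: str) -> None:
            pad = "  " * indent
            if node.feature is None:
                lines.append(f"{pad}{prefix}-> {node.prediction}")
            else:
                name = (
                    self.snp_names[node.feature]
                    if node.feature < len(self.snp_names)
                    else f"snp{node.feature}"
                )
                lines.append(f"{pad}{prefix}[{name}]")
                for v in sorted(node.children):
                    _walk(node.children[v], indent + 1, f"={v} ")

        _walk(self.root, 0, "")
        return "\n".join(lines)


def _majority(labels: np.ndarray):
    values, counts = np.unique(labels, return_counts=True)
    return values[np.argmax(counts)]  # unique() sorts, so ties -> lowest label


def build_tree(
    data: LabelledFeatureMatrix,
    criterion: str = "information_gain",
    max_depth: int = 10,
    seed: int | None = None,
    stochastic_ties: bool = False,
) -> DecisionTree:
    """Grow a decision tree on binary SNP features.

    With ``stochastic_ties`` enabled, ties in split gain are broken in a
    seeded random order instead of by lowest SNP index.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    rng = np.random.default_rng(seed)
    n_features = data.features.shape[1]

    def _nontrivial(idx: np.ndarray, f: int) -> bool:
        col = data.features[idx, f]
        return bool(col.any() and not col.all())

    def _rescue_feature(idx: np.ndarray) -> int | None:
        """One-step lookahead for parity-style patterns: a zero-gain split
        is still taken when it exposes a positive-gain split in a child."""
        for f in range(n_features):
            if not _nontrivial(idx, f):
                continue
            for v in (0, 1):
                child = idx[data.features[idx, f] == v]
                child_labels = data.labels[child]
                if np.unique(child_labels).size < 2:
                    continue
                for g in range(n_features):
                    if g != f and _split_gain(
                        data.features[child, g], child_labels, criterion
                    ) > 1e-12:
                        return f
        return None

    def grow(idx: np.ndarray, depth: int) -> _Node:
        labels = data.labels[idx]
        if np.unique(labels).size == 1 or depth >= max_depth:
            return _Node(prediction=_majority(labels))
        gains = np.array(
            [
                _split_gain(data.features[idx, f], labels, criterion)
                for f in range(n_features)
            ]
        )
        best = gains.max()
        if best <= 1e-12:
            if depth + 1 >= max_depth:
                return _Node(prediction=_majority(labels))
            feature = _rescue_feature(idx)
            if feature is None:
                return _Node(prediction=_majority(labels))
        else:
            tied = np.nonzero(np.isclose(gains, best))[0]
            feature = int(rng.choice(tied)) if stochastic_ties else int(tied[0])
        node = _Node(feature=feature, prediction=_majority(labels))
        for v in (0, 1):
            sel = idx[data.features[idx, feature] == v]
            if sel.size == 0:
                node.children[v] = _Node(prediction=_majority(labels))
            else:
                node.children[v] = grow(sel, depth + 1)
        return node

    tree = DecisionTree(criterion=criterion, max_depth=max_depth, snp_names=data.snp_names)
    tree.root = grow(np.arange(data.labels.size), 0)
    return tree


# -------------------------------------------------------------------- CV


def stratified_cv_accuracy(
    data: LabelledFeatureMatrix,
    criterion: str = "information_gain",
    max_depth: int = 10,
    k_folds: int = 5,
    repeats: int = 1,
    seed: int = 0,
    min_class_size: int | None = None,
) -> pd.DataFrame:
    """Stratified k-fold cross-validation of tree accuracy.

    Classes with fewer members than ``min_class_size`` (default
    ``k_folds``) are merged into ``wt`` with a warning column rather than
    erroring, since real cohorts contain tiny groups.  Each repeat uses a
    distinct derived seed for fold shuffling.  Returns one row per
    (repeat, fold) with the test accuracy and the number of distinct SNPs
    used by the trained tree.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    if min_class_size is None:
        min_class_size = k_folds
    labels = data.labels.copy()
    values, counts = np.unique(labels, return_counts=True)
    merged = [str(v) for v, c in zip(values, counts) if c < min_class_size]
    if merged:
        labels = np.array(["wt" if str(v) in merged else v for v in labels])
    work = LabelledFeatureMatrix(
        features=data.features, labels=labels, snp_names=data.snp_names
    )

    records = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed + rep)
        for fold, (train, test) in enumerate(skf.split(work.features, work.labels)):
            sub = LabelledFeatureMatrix(
                features=work.features[train],
                labels=work.labels[train],
                snp_names=work.snp_names,
            )
            tree = build_tree(sub, criterion=criterion, max_depth=max_depth, seed=seed + rep)
            pred = tree.predict(work.features[test])
            acc = float((pred == work.labels[test]).mean())
            records.append(
                dict(
                    repeat=rep,
                    fold=fold,
                    accuracy=acc,
                    n_snps_used=len(tree.used_features()),
                    depth=tree.depth(),
                    merged_classes=",".join(merged),
                )
            )
    return pd.DataFrame(records)


# ------------------------------------------------------------ panel table


def panel_frequency_table(
    haps: HaplotypeMatrix,
    assignment: list[str],
    gene: tuple[int, int],
    flank: int = 10_000,
    flag_threshold: float = 0.9,
) -> pd.DataFrame:
    """Per-group alt-allele frequencies for biallelic SNPs near the gene.

    Covers the gene interval plus ``flank`` bp on each side.  A SNP is
    flagged as a panel candidate when the spread between its highest and
    lowest per-group frequency is at least ``flag_threshold``.  Includes
    the information gain of each SNP on the group labels.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    start, end = gene
    rows = haps.site_index_in(start - flank, end + flank)
    mask = haps.biallelic_mask()
    rows = rows[mask[rows]]
    labels = np.array(assignment)
    groups = sorted(set(assignment))
    records = []
    for r in rows:
        carrier = haps.codes[r] > 0
        row: dict = dict(
            chrom=haps.sites[r].chrom,
            pos=haps.sites[r].pos,
            ref=haps.sites[r].ref,
            alt=haps.sites[r].alts[0],
            information_gain=information_gain(carrier.astype(int), labels),
        )
        freqs = []
        for g in groups:
            sel = labels == g
            f = float(carrier[sel].mean()) if sel.any() else float("nan")
            row[f"freq_{g}"] = f
            freqs.append(f)
        freqs = [f for f in freqs if not np.isnan(f)]
        row["flagged"] = bool(freqs and (max(freqs) - min(freqs) >= flag_threshold))
        records.append(row)
    return pd.DataFrame(records)
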