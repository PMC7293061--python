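"""Entropy, mutual information, and JMIM max-of-min feature ranking.

The feature-selection stage ranks clinical variables by the information they
share with the stress-echocardiography outcome.  Joint mutual information
maximization (JMIM) is a forward greedy filter: the first feature maximizes
the individual mutual information I(f; C); every later step picks the
candidate f_i maximizing

    min_{f_s in S} I(f_i, f_s; C)

over the already-selected set S ("maximum of the minimum" criterion), where
the pair (f_i, f_s) is treated as one variable over the product alphabet.
Because the criterion scores a candidate by its worst pairing with the
selected set, it rewards complementary features rather than individually
strong but redundant ones.

All quantities are plug-in (maximum-likelihood) estimates from contingency
counts, in bits (log base 2).  Ties at any argmax break toward the lowest
column index and are logged.

:func:`exhaustive_oracle_rank` is a structurally independent re-derivation
(explicit probability dictionaries, direct summation formulas) used only to
cross-check :func:`jmim_rank` in tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocessing import EncodedMatrix

__all__ = [
    "JointCounts",
    "RankingResult",
    "JMIMSelector",
    "entropy",
    "mutual_information",
    "joint_mutual_information",
    "jmim_rank",
    "mim_rank",
    "exhaustive_oracle_rank",
]

logger = logging.getLogger(__name__)


@dataclass
class JointCounts:
    """Contingency counts over a tuple of 1-3 discrete variables."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.counts.sum() < 1:
            raise ValueError("need at least one observation")

    @property
    def n(self) -> float:
        return float(self.counts.sum())

    @classmethod
    def from_vectors(cls, *vectors) -> "JointCounts":
        if not 1 <= len(vectors) <= 3:
            raise ValueError("JointCounts supports 1-3 variables")
        lengths = {len(v) for v in vectors}
        if len(lengths) != 1:
            raise ValueError("vectors must have equal lengths")
        codes = [pd.factorize(np.asarray(v), use_na_sentinel=False)[0] for v in vectors]
        shape = tuple(c.max() + 1 for c in codes)
        counts = np.zeros(shape)
        np.add.at(counts, tuple(codes), 1)
        return cls(counts)


def entropy(counts) -> float:
    """Shannon entropy in bits of the empirical distribution of ``counts``."""
    if isinstance(counts, JointCounts):
        c = counts.counts
    else:
        c = np.asarray(counts, dtype=float)
        if (c < 0).any():
            raise ValueError("counts must be nonnegative")
    total = c.sum()
    if total <= 0:
        raise ValueError("all-zero counts have no distribution")
    p = c[c > 0] / total
    return float(-(p * np.log2(p)).sum())


def _check_same_length(*vectors):
    lengths = {len(v) for v in vectors}
    if len(lengths) != 1:
        raise ValueError("vectors must have equal lengths")
    if lengths.pop() < 1:
        raise ValueError("vectors must be non-empty")


def mutual_information(f, c) -> float:
    """Plug-in I(F; C) in bits via H(F) + H(C) - H(F, C); clamped at 0."""
    _check_same_length(f, c)
    joint = JointCounts.from_vectors(f, c)
    h_f = entropy(joint.counts.sum(axis=1))
    h_c = entropy(joint.counts.sum(axis=0))
    mi = h_f + h_c - entropy(joint)
    return max(mi, 0.0)


def joint_mutual_information(f_i, f_s, c) -> float:
    """I((f_i, f_s); C) treating the feature pair as one product variable."""
    _check_same_length(f_i, f_s, c)
    joint = JointCounts.from_vectors(f_i, f_s, c)
    pair_counts = joint.counts.sum(axis=2)
    h_pair = entropy(pair_counts)
    h_c = entropy(joint.counts.sum(axis=(0, 1)))
    h_all = entropy(joint)
    return max(h_pair + h_c - h_all, 0.0)


@dataclass
class RankingResult:
    """Ordered feature ranking with per-step criterion values.

    ``criterion_bits[0]`` is the individual MI of the top feature; for later
    ranks it is the max-of-min objective attained at selection time.
    ``min_attained_at[r]`` names the already-selected feature achieving the
    minimum at step r (``None`` for rank 1 and for pure-MI rankings).
    """

    features: list[str]
    criterion_bits: list[float]
    min_attained_at: list[str | None] = field(default_factory=list)
    method: str = "jmim"

    def __post_init__(self):
        if len(self.features) != len(self.criterion_bits):
            raise ValueError("one criterion value per feature required")
        if any(v < 0 for v in self.criterion_bits):
            raise ValueError("criterion values must be nonnegative")
        if not self.min_attained_at:
            self.min_attained_at = [None] * len(self.features)

    def top(self, k: int) -> list[str]:
        return self.features[:k]

    def to_tsv(self, path_or_buf=None, header_comment: str | None = None):
        rows = ["rank\tfeature\tcriterion_bits\tmin_attained_at"]
        for r, (name, value, at) in enumerate(
            zip(self.features, self.criterion_bits, self.min_attained_at), start=1
        ):
            rows.append(f"{r}\t{name}\t{value:.6f}\t{at if at is not None else '-'}")
        text = "\n".join(rows) + "\n"
        if header_comment:
            text = "".join(f"# {line}\n" for line in header_comment.splitlines()) + text
        if path_or_buf is None:
            return text
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w", encoding="utf-8") as fh:
                fh.write(text)

    @classmethod
    def from_tsv(cls, path_or_buf) -> "RankingResult":
        table = pd.read_csv(path_or_buf, sep="\t", comment="#")
        return cls(
            features=list(table["feature"]),
            criterion_bits=list(table["criterion_bits"]),
            min_attained_at=[None if a == "-" else a for a in table["min_attained_at"]],
        )


def _as_xy(matrix: EncodedMatrix):
    X = matrix.X
    y = np.asarray(matrix.y)
    if X.shape[1] < 1:
        raise ValueError("need at least one feature")
    if len(np.unique(y)) < 2:
        raise ValueError("class entropy is zero: need two distinct labels")
    return X, y


class JMIMSelector:
    """sklearn-style feature selector ranking by JMIM (or plain MI).

    Parameters
    ----------
    n_features_to_select : int or None
        Size of the selected subset returned by :meth:`transform`;
        ``None`` keeps all features (the fitted ranking is still complete).
    method : {"jmim", "mim"}
        ``jmim`` applies the greedy max-of-min criterion; ``mim`` sorts by
        individual mutual information (the baseline that ignores feature
        interaction).

    Attributes
    ----------
    ranking_ : RankingResult
    feature_names_in_ : list of str
    """

    def __init__(self, n_features_to_select: int | None = None, method: str = "jmim"):
        self.n_features_to_select = n_features_to_select
        self.method = method

    def get_params(self, deep: bool = True) -> dict:
        return {"n_features_to_select": self.n_features_to_select, "method": self.method}

    def set_params(self, **params) -> "JMIMSelector":
        for k, v in params.items():
            if k not in ("n_features_to_select", "method"):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "JMIMSelector":
        if isinstance(X, EncodedMatrix):
            matrix = X
        else:
            X = pd.DataFrame(X)
            matrix = EncodedMatrix(X, np.asarray(y))
        if self.method not in ("jmim", "mim"):
            raise ValueError(f"unknown method {self.method!r}")
        self.feature_names_in_ = matrix.feature_names
        self.ranking_ = _greedy_rank(matrix, joint=(self.method == "jmim"))
        return self

    def transform(self, X):
        if not hasattr(self, "ranking_"):
            raise ValueError("JMIMSelector is not fitted")
        k = self.n_features_to_select or len(self.ranking_.features)
        keep = self.ranking_.top(k)
        if isinstance(X, EncodedMatrix):
            return X.select(keep)
        X = pd.DataFrame(X, columns=self.feature_names_in_)
        return X[keep].to_numpy()

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)


def _greedy_rank(matrix: EncodedMatrix, joint: bool) -> RankingResult:
    """Forward greedy ranking; ``joint=False`` degenerates to the MI sort."""
    X, y = _as_xy(matrix)
    names = matrix.feature_names
    cols = {name: X[name].to_numpy() for name in names}
    mi = {name: mutual_information(cols[name], y) for name in names}

    if not joint:
        order = sorted(names, key=lambda nm: (-mi[nm], names.index(nm)))
        return RankingResult(order, [mi[nm] for nm in order], method="mim")

    selected: list[str] = []
    values: list[float] = []
    attained: list[str | None] = []
    remaining = list(names)

    first = _argmax(remaining, mi)
    selected.append(first)
    values.append(mi[first])
    attained.append(None)
    remaining.remove(first)

    jmi_cache: dict[tuple[str, str], float] = {}
    while remaining:
        scores, at = {}, {}
        for cand in remaining:
            worst, worst_at = math.inf, None
            for sel in selected:
                key = (cand, sel)
                if key not in jmi_cache:
                    jmi_cache[key] = joint_mutual_information(cols[cand], cols[sel], y)
                if jmi_cache[key] < worst:
                    worst, worst_at = jmi_cache[key], sel
            scores[cand] = worst
            at[cand] = worst_at
        best = _argmax(remaining, scores)
        selected.append(best)
        values.append(scores[best])
        attained.append(at[best])
        remaining.remove(best)
    return RankingResult(selected, values, attained, method="jmim")


#: Two criterion values closer than this (bits) are treated as tied.  Exact
#: mathematical ties computed through different float paths can differ in the
#: last ulp; genuinely distinct plug-in estimates differ by far more.
TIE_TOLERANCE = 1e-9


def _argmax(candidates, scores) -> str:
    """First candidate (input order) within tolerance of the maximal score."""
    best = max(scores[c] for c in candidates)
    winners = [c for c in candidates if scores[c] >= best - TIE_TOLERANCE]
    if len(winners) > 1:
        logger.info("criterion tie at %.6f bits between %s; lowest index wins", best, winners)
    return winners[0]


def jmim_rank(matrix: EncodedMatrix) -> RankingResult:
    """Rank all features by the JMIM forward greedy max-of-min criterion."""
    return JMIMSelector(method="jmim").fit(matrix).ranking_


def mim_rank(matrix: EncodedMatrix) -> RankingResult:
    """Rank features by individual mutual information with the class."""
    return JMIMSelector(method="mim").fit(matrix).ranking_


# ---------------------------------------------------------------------------
# Independent oracle (tests only)
# ---------------------------------------------------------------------------

def _oracle_prob_table(rows) -> dict:
    """Explicit joint probability dictionary over tuples of symbols."""
    table: dict = {}
    n = len(rows)
    for row in rows:
        table[row] = table.get(row, 0) + 1
    return {k: v / n for k, v in table.items()}


def _oracle_mi(pairs) -> float:
    """Direct-sum I = sum p(f,c) log2 [p(f,c) / (p(f) p(c))]."""
    p_fc = _oracle_prob_table(pairs)
    p_f = _oracle_prob_table([f for f, _ in pairs])
    p_c = _oracle_prob_table([c for _, c in pairs])
    total = 0.0
    for (f, c), p in p_fc.items():
        total += p * math.log2(p / (p_f[f] * p_c[c]))
    return max(total, 0.0)


def exhaustive_oracle_rank(matrix: EncodedMatrix) -> RankingResult:
    """Brute-force JMIM ranking via explicit probability tables.

    Structurally independent of :func:`jmim_rank` (dictionary-based counting,
    direct-sum MI formula, itertools enumeration); limited to 8 features.
    """
    X, y = _as_xy(matrix)
    names = matrix.feature_names
    if len(names) > 8:
        raise ValueError("oracle is limited to 8 features")
    rows = {nm: [v for v in X[nm]] for nm in names}
    labels = list(y)
    n = len(labels)

    def indiv(nm):
        return _oracle_mi(list(zip(rows[nm], labels)))

    def joint(a, b):
        pairs = [((rows[a][i], rows[b][i]), labels[i]) for i in range(n)]
        return _oracle_mi(pairs)

    def pick(cands, value_of):
        scored = [(nm, value_of(nm)) for nm in cands]
        top = max(v for _, v in scored)
        for nm, v in scored:  # first within tolerance of the max (lowest index)
            if v >= top - TIE_TOLERANCE:
                return nm, v

    selected, values, attained = [], [], []
    remaining = list(names)
    best, best_val = pick(remaining, indiv)
    selected.append(best)
    values.append(best_val)
    attained.append(None)
    remaining.remove(best)

    while remaining:
        worst_of = {}
        for cand in remaining:
            pair_vals = [(joint(cand, sel), sel) for sel in selected]
            worst_of[cand] = min(pair_vals, key=lambda t: t[0])
        best, best_val = pick(remaining, lambda nm: worst_of[nm][0])
        selected.append(best)
        values.append(best_val)
        attained.append(worst_of[best][1])
        remaining.remove(best)
    return RankingResult(selected, values, attained, method="oracle")
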