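"""RBP binding-site discrimination on RNA secondary-structure graphs.

Two RBPs in a mined cluster either bind distinct regions (their sites are
easy to tell apart) or compatible ones (hard to tell apart, hinting at
cooperative or competitive binding).  The module casts this as binary
classification: sample fixed-length site sequences per RBP, predict a small
set of secondary structures for each, encode every site as a disconnected
graph (one component per sampled structure; vertices = nucleotides, edges =
backbone or base-pair bonds), extract neighborhood-subgraph pairwise-distance
kernel (NSPDK) features, and train a linear SVM by stochastic gradient
descent.  Pairwise AUROCC near 0.5 flags compatible binding preferences;
values near 1 flag well-separated sites.

The built-in folding backend is a Nussinov maximum-base-pairing sampler
(canonical pairs AU/GC/GU, minimum hairpin loop of 3) with stochastic
traceback over co-optimal structures; dot-bracket input gives parity with
any external thermodynamic folder.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

RNA_ALPHABET = set("ACGU")
CANONICAL_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
MIN_HAIRPIN_LOOP = 3  # unpaired bases required inside a hairpin


@dataclass(frozen=True)
class SiteSequence:
    site_id: str
    rbp_id: str
    sequence: str
    source: tuple | None = None  # (sequence_id, start, end), 0-based half-open

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - RNA_ALPHABET
        if bad:
            raise ValueError(f"invalid nucleotides {sorted(bad)} in site {self.site_id}")

    def __len__(self) -> int:
        return len(self.sequence)


def sample_sites(
    sites: Sequence[SiteSequence],
    n: int,
    min_len: int = 20,
    max_len: int = 70,
    seed: int = 0,
) -> list[SiteSequence]:
    """Uniform sample without replacement of sites within the length bounds.

    If fewer than ``n`` sites qualify, all of them are returned with a
    warning.  Deterministic given the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    pool = [s for s in sites if min_len <= len(s) <= max_len]
    if not pool:
        raise ValueError(f"no site has length in [{min_len}, {max_len}]")
    if len(pool) <= n:
        if len(pool) < n:
            logger.warning("only %d of the requested %d sites qualify", len(pool), n)
        return list(pool)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in sorted(idx)]


# --- folding -----------------------------------------------------------------


def _nussinov_table(seq: str) -> np.ndarray:
    """DP table of maximum base-pair counts over all substrings."""
    L = len(seq)
    N = np.zeros((L, L), dtype=np.int32)
    for span in range(MIN_HAIRPIN_LOOP + 1, L):
        for i in range(L - span):
            j = i + span
            best = N[i, j - 1]  # j unpaired
            for k in range(i, j - MIN_HAIRPIN_LOOP):
                if (seq[k], seq[j]) in CANONICAL_PAIRS:
                    left = N[i, k - 1] if k > i else 0
                    inner = N[k + 1, j - 1] if k + 1 <= j - 1 else 0
                    best = max(best, left + inner + 1)
            N[i, j] = best
    return N


def _traceback(seq: str, N: np.ndarray, rng: np.random.Generator) -> list[tuple[int, int]]:
    """One uniform-at-each-branch stochastic traceback of co-optimal pairings."""
    pairs: list[tuple[int, int]] = []
    stack = [(0, len(seq) - 1)]
    while stack:
        i, j = stack.pop()
        if j - i < MIN_HAIRPIN_LOOP + 1:
            continue
        options = []
        if N[i, j] == N[i, j - 1]:
            options.append(None)
        for k in range(i, j - MIN_HAIRPIN_LOOP):
            if (seq[k], seq[j]) in CANONICAL_PAIRS:
                left = N[i, k - 1] if k > i else 0
                inner = N[k + 1, j - 1] if k + 1 <= j - 1 else 0
                if left + inner + 1 == N[i, j]:
                    options.append(k)
        choice = options[rng.integers(len(options))]
        if choice is None:
            stack.append((i, j - 1))
        else:
            k = choice
            pairs.append((k, j))
            if k > i:
                stack.append((i, k - 1))
            if k + 1 <= j - 1:
                stack.append((k + 1, j - 1))
    return sorted(pairs)


def parse_dotbracket(db: str) -> list[tuple[int, int]]:
    """Base pairs (0-based) from a dot-bracket string; raises on imbalance."""
    stack: list[int] = []
    pairs = []
    for i, ch in enumerate(db):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i} in {db!r}")
            pairs.append((stack.pop(), i))
        elif ch != ".":
            raise ValueError(f"unexpected character {ch!r} in dot-bracket string")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]} in {db!r}")
    return sorted(pairs)


def fold_to_graph(
    seq: str,
    backend: str = "builtin_nussinov",
    n_structures: int = 3,
    seed: int = 0,
    structures: Iterable[str] | None = None,
    max_retries: int = 20,
) -> nx.Graph:
    """Encode a site and a sample of its secondary structures as one graph.

    Each sampled structure contributes one connected component: a backbone
    path over the nucleotides plus base-pair edges.  Node attribute
    ``label`` is the nucleotide, edge attribute ``label`` is ``backbone`` or
    ``basepair``.
    """
    seq = seq.upper().replace("T", "U")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValueError(f"invalid nucleotides {sorted(bad)}")
    if backend == "path_only":
        pair_sets: list[list[tuple[int, int]]] = [[]]
    elif backend == "dotbracket_input":
        if structures is None:
            raise ValueError("dotbracket_input backend requires structures")
        pair_sets = []
        for db in structures:
            if len(db) != len(seq):
                raise ValueError("dot-bracket length does not match sequence")
            pair_sets.append(parse_dotbracket(db))
    elif backend == "builtin_nussinov":
        N = _nussinov_table(seq)
        rng = np.random.default_rng(seed)
        seen: list[list[tuple[int, int]]] = []
        seen_keys: set[tuple] = set()
        tries = 0
        while len(seen) < n_structures and tries < n_structures * max_retries:
            pairs = _traceback(seq, N, rng)
            key = tuple(pairs)
            if key not in seen_keys:
                seen_keys.add(key)
                seen.append(pairs)
            tries += 1
        pair_sets = seen
    else:
        raise ValueError(f"unknown folding backend {backend!r}")

    g = nx.Graph()
    for comp, pairs in enumerate(pair_sets):
        nodes = [(comp, i) for i in range(len(seq))]
        for i, node in enumerate(nodes):
            g.add_node(node, label=seq[i])
        for i in range(len(seq) - 1):
            g.add_edge(nodes[i], nodes[i + 1], label="backbone")
        for i, j in pairs:
            g.add_edge(nodes[i], nodes[j], label="basepair")
    return g


# --- NSPDK features ----------------------------------------------------------


@dataclass(frozen=True)
class KernelParams:
    max_radius: int = 2   # R: neighborhood-subgraph radius bound
    max_distance: int = 4  # D: root-pair distance bound
    hash_bits: int = 20   # feature space size 2^bits
    normalize: bool = True  # per-(r,d)-block L2, then global L2

    def __post_init__(self) -> None:
        if self.max_radius < 0 or self.max_distance < 0:
            raise ValueError("R and D must be >= 0")
        if not (8 <= self.hash_bits <= 30):
            raise ValueError("hash_bits must be in [8, 30]")

    @property
    def n_features(self) -> int:
        return (self.max_radius + 1) * (self.max_distance + 1) * (1 << self.hash_bits)


def _h64(*parts) -> int:
    """Stable 64-bit hash of a tuple of hashable parts (seed-independent)."""
    return int.from_bytes(
        hashlib.blake2b(repr(parts).encode(), digest_size=8).digest(), "big"
    )


def _neighborhood_certificates(
    g: nx.Graph, dist: Mapping, root, max_radius: int
) -> list[int]:
    """Quasi-canonical label of the radius-r ball around ``root``, r = 0..R.

    Iterative label refinement (r rounds at radius r) over the ball, seeded
    with (distance-to-root, vertex label) and folding in edge labels each
    round — invariant under vertex reordering by construction.
    """
    droot = dist[root]
    certs = []
    for r in range(max_radius + 1):
        ball = [v for v, d in droot.items() if d <= r]
        labels = {v: _h64("init", droot[v], g.nodes[v]["label"]) for v in ball}
        ball_set = set(ball)
        for _ in range(r):
            new = {}
            for v in ball:
                neigh = sorted(
                    (g.edges[v, w]["label"], labels[w])
                    for w in g.neighbors(v)
                    if w in ball_set
                )
                new[v] = _h64("ref", labels[v], tuple(neigh))
            labels = new
        certs.append(_h64("ball", r, tuple(sorted(labels.values()))))
    return certs


def nspdk_features(g: nx.Graph, params: KernelParams) -> dict[int, float]:
    """Sparse hashed NSPDK feature vector of a labeled graph.

    For every unordered pair of vertices in the same component at shortest-
    path distance d ≤ D and every radius r ≤ R, the pair of quasi-canonical
    neighborhood-subgraph labels is hashed into one of 2^bits bins of the
    (r, d) block.  Empty graphs yield the zero vector.
    """
    if g.number_of_nodes() == 0:
        return {}
    R, D = params.max_radius, params.max_distance
    horizon = max(R, D)
    dist = {
        v: dict(nx.single_source_shortest_path_length(g, v, cutoff=horizon))
        for v in g.nodes
    }
    certs = {v: _neighborhood_certificates(g, dist, v, R) for v in g.nodes}
    nbins = 1 << params.hash_bits
    raw: dict[int, float] = {}
    order = {v: i for i, v in enumerate(g.nodes)}
    for u in g.nodes:
        for v, d in dist[u].items():
            if d > D or order[v] < order[u]:
                continue
            for r in range(R + 1):
                cu, cv = certs[u][r], certs[v][r]
                if cu > cv:
                    cu, cv = cv, cu
                block = r * (D + 1) + d
                idx = block * nbins + (_h64("pair", cu, cv, d, r) % nbins)
                raw[idx] = raw.get(idx, 0.0) + 1.0
    if not params.normalize:
        return raw
    # per-(r,d)-block L2, then global L2
    norms: dict[int, float] = {}
    for idx, val in raw.items():
        b = idx // nbins
        norms[b] = norms.get(b, 0.0) + val * val
    out = {idx: val / math.sqrt(norms[idx // nbins]) for idx, val in raw.items()}
    total = math.sqrt(sum(v * v for v in out.values()))
    return {idx: v / total for idx, v in out.items()}


def features_to_matrix(
    feature_dicts: Sequence[dict[int, float]], params: KernelParams
) -> csr_matrix:
    """Stack sparse feature dicts into a CSR design matrix."""
    indptr = [0]
    indices: list[int] = []
    data: list[float] = []
    for fd in feature_dicts:
        for idx in sorted(fd):
            indices.append(idx)
            data.append(fd[idx])
        indptr.append(len(indices))
    return csr_matrix(
        (data, indices, indptr), shape=(len(feature_dicts), params.n_features)
    )


def kernel_value(fa: dict[int, float], fb: dict[int, float]) -> float:
    """Dot product of two sparse feature vectors (the kernel evaluation)."""
    if len(fb) < len(fa):
        fa, fb = fb, fa
    return sum(v * fb.get(k, 0.0) for k, v in fa.items())


# --- classification ----------------------------------------------------------


@dataclass(frozen=True)
class SVMConfig:
    lam: float = 1e-4   # SGD regularization (sklearn alpha)
    epochs: int = 100
    folds: int = 10
    seed: int = 0
    n_structures: int = 3  # sampled structures per site for the built-in folder


@dataclass
class ClassificationReport:
    rbp_pair: tuple[str, str]
    auroc: float
    f1: float
    precision: float
    sensitivity: float
    folds: int
    per_fold_auroc: list[float]
    tp: int
    fp: int
    tn: int
    fn: int


def evaluate(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[float, float, float, float, int, int, int, int]:
    """AUROCC (Mann–Whitney rank statistic, ties averaged) and threshold-0
    confusion metrics.

    Returns (auroc, f1, precision, sensitivity, TP, FP, TN, FN).  Predictions
    are positive when the score is > 0.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    npos, nneg = int(labels.sum()), int((~labels).sum())
    if npos == 0 or nneg == 0:
        raise ValueError("AUROCC undefined: both classes must be present")
    ranks = rankdata(scores)
    auroc = (ranks[labels].sum() - npos * (npos + 1) / 2) / (npos * nneg)
    pred = scores > 0
    tp = int(np.sum(pred & labels))
    fp = int(np.sum(pred & ~labels))
    tn = int(np.sum(~pred & ~labels))
    fn = int(np.sum(~pred & labels))
    precision = tp / (tp + fp) if tp + fp else 0.0
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    denom = precision + sensitivity
    f1 = 2 * precision * sensitivity / denom if denom else 0.0
    return float(auroc), f1, precision, sensitivity, tp, fp, tn, fn


def site_features(
    sites: Sequence[SiteSequence],
    params: KernelParams,
    backend: str = "builtin_nussinov",
    n_structures: int = 3,
    seed: int = 0,
) -> list[dict[int, float]]:
    """Fold each site and extract its NSPDK feature vector.

    Per-site fold seeds derive deterministically from ``seed`` and the site
    index, so the encoding is reproducible and independent of other sites.
    """
    return [
        nspdk_features(
            fold_to_graph(s.sequence, backend=backend, n_structures=n_structures,
                          seed=(seed * 1_000_003 + i) % (2**31)),
            params,
        )
        for i, s in enumerate(sites)
    ]


def train_pairwise(
    sitesA: Sequence[SiteSequence],
    sitesB: Sequence[SiteSequence],
    params: KernelParams = KernelParams(),
    svm_config: SVMConfig = SVMConfig(),
    pair_name: tuple[str, str] | None = None,
    backend: str = "builtin_nussinov",
) -> ClassificationReport:
    """Cross-validated linear-SVM discrimination of two RBPs' sites.

    Class A is labeled positive.  Per fold an unbiased hinge-loss linear
    model is trained by SGD on the hashed NSPDK features and held-out sites
    are scored; the report carries the mean per-fold AUROCC and F1/precision/
    sensitivity at decision threshold 0 on the pooled held-out predictions.
    """
    from sklearn.linear_model import SGDClassifier
    from sklearn.model_selection import StratifiedKFold

    if not sitesA or not sitesB:
        raise ValueError("both site sets must be non-empty")
    folds = svm_config.folds
    if min(len(sitesA), len(sitesB)) < folds:
        raise ValueError(
            f"smallest class has {min(len(sitesA), len(sitesB))} sites; "
            f"use fewer than {folds} folds"
        )
    feats = site_features(
        list(sitesA) + list(sitesB), params,
        backend=backend, n_structures=svm_config.n_structures, seed=svm_config.seed,
    )
    X = features_to_matrix(feats, params)
    y = np.array([1] * len(sitesA) + [0] * len(sitesB))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=svm_config.seed % (2**31))
    fold_auroc = []
    pooled_scores = np.zeros(len(y))
    for f, (train, test) in enumerate(skf.split(X, y)):
        clf = SGDClassifier(
            loss="hinge",
            alpha=svm_config.lam,
            max_iter=svm_config.epochs,
            tol=None,
            fit_intercept=False,
            random_state=(svm_config.seed + f) % (2**31),
        )
        clf.fit(X[train], y[train])
        s = clf.decision_function(X[test])
        pooled_scores[test] = s
        auroc, *_ = evaluate(s, y[test])
        fold_auroc.append(auroc)
    auroc, f1, precision, sensitivity, tp, fp, tn, fn = evaluate(pooled_scores, y)
    name = pair_name or (
        sitesA[0].rbp_id if sitesA else "A",
        sitesB[0].rbp_id if sitesB else "B",
    )
    return ClassificationReport(
        rbp_pair=name,
        auroc=float(np.mean(fold_auroc)),
        f1=f1,
        precision=precision,
        sensitivity=sensitivity,
        folds=folds,
        per_fold_auroc=fold_auroc,
        tp=tp, fp=fp, tn=tn, fn=fn,
    )


def pairwise_report(
    rbp_sites: Mapping[str, Sequence[SiteSequence]],
    params: KernelParams = KernelParams(),
    svm_config: SVMConfig = SVMConfig(),
    backend: str = "builtin_nussinov",
) -> tuple[dict[tuple[str, str], ClassificationReport], pd.DataFrame]:
    """One classifier per unordered RBP pair, plus the half-matrix table.

    When site pools differ in size the larger one is downsampled to the
    smaller with the run seed, keeping the pair task class-balanced.  The
    returned DataFrame carries AUROCC in the upper triangle and F1 in the
    lower one, as the pairwise performance tables are conventionally printed.
    """
    rbps = sorted(rbp_sites)
    if len(rbps) < 2:
        raise ValueError("need at least two RBPs with sites")
    reports: dict[tuple[str, str], ClassificationReport] = {}
    M = pd.DataFrame(np.nan, index=rbps, columns=rbps)
    for a, b in itertools.combinations(rbps, 2):
        sa, sb = list(rbp_sites[a]), list(rbp_sites[b])
        n = min(len(sa), len(sb))
        if len(sa) > n:
            sa = sample_sites(sa, n, min_len=0, max_len=10**9, seed=svm_config.seed)
        if len(sb) > n:
            sb = sample_sites(sb, n, min_len=0, max_len=10**9, seed=svm_config.seed)
        rep = train_pairwise(sa, sb, params, svm_config, pair_name=(a, b), backend=backend)
        reports[(a, b)] = rep
        M.loc[a, b] = rep.auroc  # upper triangle: AUROCC
        M.loc[b, a] = rep.f1     # lower triangle: F1
    return reports, M


# --- binding-site distances --------------------------------------------------


def site_distance_distribution(
    sitesA: Sequence[SiteSequence],
    sitesB: Sequence[SiteSequence],
    mode: str = "midpoint",
) -> tuple[list[float], dict]:
    """Distances between A/B site pairs sharing a transcript.

    ``midpoint``: |midpoint(A) − midpoint(B)| in nt; ``gap``: edge-to-edge
    separation, 0 for overlapping or abutting sites.  Returns the flat list
    of distances over all cross pairs on shared transcripts, plus summary
    statistics.
    """
    if mode not in ("midpoint", "gap"):
        raise ValueError("mode must be 'midpoint' or 'gap'")
    byA: dict[str, list[SiteSequence]] = {}
    for s in sitesA:
        if s.source is not None:
            byA.setdefault(s.source[0], []).append(s)
    dists: list[float] = []
    for s in sitesB:
        if s.source is None or s.source[0] not in byA:
            continue
        for a in byA[s.source[0]]:
            _, a0, a1 = a.source
            _, b0, b1 = s.source
            if mode == "midpoint":
                dists.append(abs((a0 + a1) / 2 - (b0 + b1) / 2))
            else:
                dists.append(float(max(0, max(a0, b0) - min(a1, b1))))
    if not dists:
        logger.warning("no shared transcripts between the two site sets")
        stats = {"n": 0, "mean": float("nan"), "median": float("nan"), "std": float("nan")}
    else:
        arr = np.asarray(dists)
        stats = {
            "n": len(dists),
            "mean": float(arr.mean()),
            "median": float(np.median(arr)),
            "std": float(arr.std(ddof=1)) if len(dists) > 1 else 0.0,
        }
    return dists, stats
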