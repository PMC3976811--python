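"""Codon-level selection analysis: GY94 site models, LRTs and positive sites.

The substitution process is the Goldman-Yang codon model: instantaneous
rates between sense codons differing at a single nucleotide are

    q_ij = pi_j            (synonymous transversion)
         = pi_j * kappa    (synonymous transition)
         = pi_j * omega    (nonsynonymous transversion)
         = pi_j * omega * kappa  (nonsynonymous transition)

scaled so the expected rate is one substitution per codon per unit branch
length.  Site-to-site variation in omega follows the standard site models:

* M0 — one omega for all sites;
* M3 — K = 3 discrete omega classes with free weights;
* M7 — omega ~ Beta(p, q), discretised into 10 equal-probability classes;
* M8 — a proportion p0 of sites from Beta(p, q) plus a class at omega_s >= 1.

Nested pairs (M0 in M3, df 4; M7 in M8, df 2) are compared by likelihood
ratio test against chi-square.  Sites under positive selection are called
by naive empirical Bayes (NEB): per-site class posteriors at the MLEs,
thresholded on the total posterior mass of omega > 1 classes.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from Bio.Data import CodonTable

from .tree import TreeNode

_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = set(_TABLE.stop_codons)
NUCS = "TCAG"
CODONS = [
    a + b + c
    for a in NUCS
    for b in NUCS
    for c in NUCS
    if a + b + c not in STOP_CODONS
]
N_CODONS = len(CODONS)                      # 61
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
CODON_AA = {c: _TABLE.forward_table[c] for c in CODONS}

_TS_PAIRS = {frozenset("AG"), frozenset("CT")}

N_BETA_CATEGORIES = 10


def is_transition(x: str, y: str) -> bool:
    return frozenset((x, y)) in _TS_PAIRS


# ---------------------------------------------------------------------------
# Codon alignments

@dataclass
class CodonAlignment:
    """Aligned codon columns over taxa; gaps/ambiguities are masked (-1)."""

    taxa: list[str]
    codon_indices: np.ndarray               # (ntaxa, nsites) int, -1 = missing

    def __post_init__(self) -> None:
        self.codon_indices = np.asarray(self.codon_indices, dtype=int)
        if self.codon_indices.shape[0] != len(self.taxa):
            raise ValueError("codon matrix row count != number of taxa")

    @property
    def n_sites(self) -> int:
        return self.codon_indices.shape[1]

    @classmethod
    def from_sequences(cls, records: Iterable[tuple[str, str]]) -> "CodonAlignment":
        """Build from aligned nucleotide sequences (length divisible by 3).

        Stop codons in the data are rejected — stop-carrying (pseudogene)
        sequences are expected to be excluded upstream.
        """
        taxa, rows = [], []
        length = None
        for name, seq in records:
            seq = seq.upper().replace("U", "T")
            if len(seq) % 3:
                raise ValueError(f"{name}: aligned CDS length not divisible by 3")
            if length is None:
                length = len(seq)
            elif len(seq) != length:
                raise ValueError("aligned sequences must have equal length")
            row = []
            for k in range(0, len(seq), 3):
                codon = seq[k:k + 3]
                if codon in STOP_CODONS:
                    raise ValueError(f"{name}: stop codon {codon} at codon {k // 3}")
                row.append(CODON_INDEX.get(codon, -1))
            taxa.append(name)
            rows.append(row)
        return cls(taxa, np.array(rows))

    def codon_strings(self) -> list[tuple[str, str]]:
        out = []
        for t, row in zip(self.taxa, self.codon_indices):
            out.append(
                (t, "".join(CODONS[i] if i >= 0 else "---" for i in row))
            )
        return out

    def translate(self) -> list[tuple[str, str]]:
        out = []
        for t, row in zip(self.taxa, self.codon_indices):
            out.append(
                (t, "".join(CODON_AA[CODONS[i]] if i >= 0 else "-" for i in row))
            )
        return out

    def f3x4(self, floor: float = 1e-8) -> np.ndarray:
        """F3x4 equilibrium codon frequencies from positional nucleotide
        frequencies of the data (stop codons zeroed, renormalised)."""
        pos_counts = np.full((3, 4), floor)
        nuc_index = {n: i for i, n in enumerate(NUCS)}
        for row in self.codon_indices:
            for idx in row:
                if idx < 0:
                    continue
                for p, ch in enumerate(CODONS[idx]):
                    pos_counts[p, nuc_index[ch]] += 1.0
        pos_freq = pos_counts / pos_counts.sum(axis=1, keepdims=True)
        pi = np.array(
            [
                pos_freq[0, nuc_index[c[0]]]
                * pos_freq[1, nuc_index[c[1]]]
                * pos_freq[2, nuc_index[c[2]]]
                for c in CODONS
            ]
        )
        pi = np.maximum(pi, floor)
        return pi / pi.sum()


def backtranslate(
    protein_msa: Sequence[tuple[str, str]],
    cds_map: dict[str, str],
) -> CodonAlignment:
    """Expand an aligned protein MSA to codons using each taxon's CDS.

    Each CDS must translate exactly to its ungapped protein (a terminal stop
    codon and a trailing ``*`` are tolerated); mismatches raise an error
    naming the taxon and the offending protein position.
    """
    taxa, rows = [], []
    for name, aligned in protein_msa:
        if name not in cds_map:
            raise ValueError(f"backtranslate: no CDS for taxon {name!r}")
        cds = cds_map[name].upper().replace("U", "T")
        ungapped = aligned.replace("-", "").upper().rstrip("*")
        codons = [cds[k:k + 3] for k in range(0, len(cds) - len(cds) % 3, 3)]
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        if len(codons) != len(ungapped):
            raise ValueError(
                f"backtranslate: {name}: CDS has {len(codons)} codons but "
                f"protein has {len(ungapped)} residues"
            )
        for pos, (aa, codon) in enumerate(zip(ungapped, codons)):
            trans = CODON_AA.get(codon)
            if trans is None:
                raise ValueError(
                    f"backtranslate: {name}: internal stop/invalid codon "
                    f"{codon} at protein position {pos}"
                )
            if trans != aa:
                raise ValueError(
                    f"backtranslate: {name}: codon {codon} translates to "
                    f"{trans}, protein has {aa} at position {pos}"
                )
        row, k = [], 0
        for aa in aligned:
            if aa == "-":
                row.append(-1)
            else:
                row.append(CODON_INDEX[codons[k]])
                k += 1
        taxa.append(name)
        rows.append(row)
    return CodonAlignment(taxa, np.array(rows))


# ---------------------------------------------------------------------------
# GY94 rate matrix

def gy94_Q(kappa: float, omega: float, codon_freqs: np.ndarray) -> np.ndarray:
    """Scaled GY94 generator (61x61); mean rate one substitution/codon/unit t."""
    pi = np.asarray(codon_freqs, dtype=float)
    if pi.shape != (N_CODONS,) or (pi < 0).any() or abs(pi.sum() - 1) > 1e-8:
        raise ValueError("codon_freqs must be a simplex over the 61 sense codons")
    if kappa <= 0 or omega < 0:
        raise ValueError("require kappa > 0 and omega >= 0")
    Q = np.zeros((N_CODONS, N_CODONS))
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diffs = [(x, y) for x, y in zip(ci, cj) if x != y]
            if len(diffs) != 1:
                continue
            rate = pi[j]
            if is_transition(*diffs[0]):
                rate *= kappa
            if CODON_AA[ci] != CODON_AA[cj]:
                rate *= omega
            Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -(pi * np.diag(Q)).sum()
    if mean_rate > 0:
        Q /= mean_rate
    return Q


class _EigenCache:
    """P(t) factory; reuses the symmetric eigendecomposition per (kappa, omega)."""

    def __init__(self, pi: np.ndarray):
        self.pi = pi
        self.sqrt_pi = np.sqrt(pi)
        self._cache: dict[tuple[float, float], tuple] = {}

    def _decompose(self, kappa: float, omega: float):
        key = (kappa, omega)
        if key not in self._cache:
            Q = gy94_Q(kappa, omega, self.pi)
            B = (self.sqrt_pi[:, None] * Q) / self.sqrt_pi[None, :]
            w, U = np.linalg.eigh((B + B.T) / 2.0)
            left = U / self.sqrt_pi[:, None]
            right = (U * self.sqrt_pi[:, None]).T
            self._cache[key] = (w, left, right)
        return self._cache[key]

    def transition_matrix(self, kappa: float, omega: float, t: float) -> np.ndarray:
        w, left, right = self._decompose(kappa, omega)
        P = (left * np.exp(w * t)[None, :]) @ right
        np.maximum(P, 0.0, out=P)
        return P


# ---------------------------------------------------------------------------
# Likelihood

def _compress(aln: CodonAlignment) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique site patterns, their counts, and site -> pattern index."""
    cols = aln.codon_indices.T
    patterns, inverse, counts = np.unique(
        cols, axis=0, return_inverse=True, return_counts=True
    )
    return patterns.T, counts, inverse


def _leaf_partials(patterns: np.ndarray) -> np.ndarray:
    """(ntaxa, 61, npatterns) leaf conditionals; missing data = all ones."""
    ntaxa, npat = patterns.shape
    out = np.zeros((ntaxa, N_CODONS, npat))
    for t in range(ntaxa):
        for p in range(npat):
            idx = patterns[t, p]
            if idx < 0:
                out[t, :, p] = 1.0
            else:
                out[t, idx, p] = 1.0
    return out


class CodonLikelihood:
    """Felsenstein pruning for a fixed alignment/tree pair.

    Branch lengths are read from the tree each call (optionally times a
    global scale), so optimisers can mutate them in place.
    """

    def __init__(self, aln: CodonAlignment, tree: TreeNode,
                 codon_freqs: Optional[np.ndarray] = None):
        leaf_names = sorted(tree.leaf_names())
        if leaf_names != sorted(aln.taxa):
            raise ValueError(
                f"tree leaves {leaf_names} do not match alignment taxa "
                f"{sorted(aln.taxa)}"
            )
        self.aln = aln
        self.tree = tree
        self.pi = aln.f3x4() if codon_freqs is None else np.asarray(codon_freqs)
        self.patterns, self.counts, self.site_to_pattern = _compress(aln)
        taxon_row = {t: i for i, t in enumerate(aln.taxa)}
        self._leaf_row = {
            id(n): taxon_row[n.name] for n in tree.walk() if n.is_leaf
        }
        self._leaves = _leaf_partials(self.patterns)
        self.cache = _EigenCache(self.pi)
        self.n_branches = sum(1 for n in tree.walk() if n is not tree)

    def branches(self) -> list[TreeNode]:
        return [n for n in self.tree.walk() if n is not self.tree]

    def _conditional(self, node: TreeNode, kappa: float, omega: float,
                     scale: float) -> tuple[np.ndarray, np.ndarray]:
        if node.is_leaf:
            return self._leaves[self._leaf_row[id(node)]], 0.0
        part = None
        log_scale = 0.0
        for child in node.children:
            cpart, cscale = self._conditional(child, kappa, omega, scale)
            t = max(child.length or 0.0, 0.0) * scale
            P = self.cache.transition_matrix(kappa, omega, t)
            term = P @ cpart
            part = term if part is None else part * term
            log_scale = log_scale + cscale
        peak = part.max(axis=0)
        peak = np.where(peak > 0, peak, 1.0)
        part = part / peak
        return part, log_scale + np.log(peak)

    def class_site_loglik(self, kappa: float, omega: float,
                          scale: float = 1.0) -> np.ndarray:
        """Per-pattern log-likelihood under a single omega class."""
        part, log_scale = self._conditional(self.tree, kappa, omega, scale)
        site_l = self.pi @ part
        return np.log(np.maximum(site_l, 1e-300)) + log_scale

    def log_likelihood(
        self,
        kappa: float,
        categories: Sequence[tuple[float, float]],
        scale: float = 1.0,
        return_site_matrix: bool = False,
    ):
        """Mixture log-likelihood over omega classes.

        ``categories`` are (weight, omega) pairs summing to 1.  With
        ``return_site_matrix`` also returns the (ncats, nsites) per-class
        per-site log-likelihoods (pattern-expanded).
        """
        weights = np.array([w for w, _ in categories])
        if abs(weights.sum() - 1.0) > 1e-6:
            raise ValueError("mixture weights must sum to 1")
        per_class = np.vstack(
            [self.class_site_loglik(kappa, om, scale) for _, om in categories]
        )
        m = per_class.max(axis=0)
        mixed = m + np.log(
            np.maximum((weights[:, None] * np.exp(per_class - m)).sum(axis=0), 1e-300)
        )
        lnl = float((self.counts * mixed).sum())
        if return_site_matrix:
            return lnl, per_class[:, self.site_to_pattern]
        return lnl


# ---------------------------------------------------------------------------
# Site models

def beta_bin_means(p: float, q: float, k: int = N_BETA_CATEGORIES) -> np.ndarray:
    """Means of Beta(p, q) within k equal-probability bins."""
    edges = stats.beta.ppf(np.linspace(0.0, 1.0, k + 1), p, q)
    upper = special.betainc(p + 1.0, q, edges[1:])
    lower = special.betainc(p + 1.0, q, edges[:-1])
    means = (upper - lower) * (p / (p + q)) * k
    return np.clip(means, 1e-8, 1.0)


def model_categories(model: str, params: dict) -> list[tuple[float, float]]:
    """(weight, omega) classes for a model given its parameter dict."""
    if model == "M0":
        return [(1.0, params["omega"])]
    if model == "M3":
        weights = params["weights"]
        omegas = params["omegas"]
        return list(zip(weights, omegas))
    if model == "M7":
        means = beta_bin_means(params["p"], params["q"])
        return [(1.0 / len(means), float(m)) for m in means]
    if model == "M8":
        means = beta_bin_means(params["p"], params["q"])
        p0 = params["p0"]
        cats = [(p0 / len(means), float(m)) for m in means]
        cats.append((1.0 - p0, params["omega_s"]))
        return cats
    raise ValueError(f"unknown site model {model!r}")


@dataclass
class SiteModelFit:
    model: str
    kappa: float
    params: dict
    lnl: float
    tree: TreeNode
    branch_scale: float
    categories: list[tuple[float, float]]
    site_posteriors: np.ndarray = field(repr=False, default=None)
    converged: bool = True
    flags: list[str] = field(default_factory=list)

    @property
    def branch_lengths(self) -> dict[str, float]:
        out = {}
        for i, node in enumerate(n for n in self.tree.walk() if n is not self.tree):
            key = node.name or f"internal_{i}"
            out[key] = (node.length or 0.0) * self.branch_scale
        return out


@dataclass
class LrtResult:
    null_model: str
    alt_model: str
    stat: float
    df: int
    p_value: float


_NESTED_PAIRS = {("M0", "M3"): 4, ("M7", "M8"): 2}

KAPPA_BOUNDS = (0.1, 20.0)
OMEGA_BOUNDS = (1e-4, 50.0)
BETA_BOUNDS = (0.05, 99.0)
BRANCH_BOUNDS = (1e-8, 20.0)
SCALE_BOUNDS = (1e-3, 100.0)


class _BestTracker:
    """Record the best parameter vector ever evaluated by the optimiser."""

    def __init__(self, fun):
        self.fun = fun
        self.best_x = None
        self.best_f = np.inf

    def __call__(self, x):
        f = self.fun(x)
        if f < self.best_f:
            self.best_f = f
            self.best_x = np.array(x)
        return f


def _minimize(tracker: _BestTracker, x0: np.ndarray, bounds) -> bool:
    res = optimize.minimize(
        tracker, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-10},
    )
    return bool(res.success)


def fit_site_model(
    aln: CodonAlignment,
    tree: TreeNode,
    model: str = "M0",
    codon_freqs: Optional[np.ndarray] = None,
    null_fit: Optional[SiteModelFit] = None,
    n_starts: int = 3,
) -> SiteModelFit:
    """Maximum-likelihood fit of one site model.

    M0 optimises kappa, omega and every branch length jointly from
    ``n_starts`` fixed starting points.  The richer models keep the M0
    branch-length proportions (pass ``null_fit``; fitted internally when
    absent) and optimise kappa, a global branch scale and the model's
    omega-distribution parameters, starting from the null model's optimum
    so nesting (lnL alt >= lnL null) holds by construction.
    """
    if model == "M0":
        return _fit_m0(aln, tree, codon_freqs, n_starts)
    if model in ("M3", "M7", "M8"):
        if model == "M3" and (null_fit is None or null_fit.model != "M0"):
            null_fit = _fit_m0(aln, tree, codon_freqs, n_starts)
        if model == "M8" and (null_fit is None or null_fit.model != "M7"):
            null_fit = fit_site_model(aln, tree, "M7", codon_freqs)
        if model == "M7" and (null_fit is None or null_fit.model != "M0"):
            null_fit = _fit_m0(aln, tree, codon_freqs, n_starts)
        return _fit_mixture(aln, model, codon_freqs, null_fit)
    raise ValueError(f"unknown site model {model!r}")


_M0_STARTS = [(2.0, 0.4), (1.0, 1.0), (4.0, 0.1)]


def _fit_m0(aln, tree, codon_freqs, n_starts) -> SiteModelFit:
    work_tree = copy.deepcopy(tree)
    for node in work_tree.walk():
        if node is not work_tree:
            if node.length is None or node.length <= 0:
                node.length = 0.1
    engine = CodonLikelihood(aln, work_tree, codon_freqs)
    branches = engine.branches()
    nb = len(branches)

    def unpack(x):
        return math.exp(x[0]), math.exp(x[1]), np.exp(x[2:])

    def objective(x):
        kappa, omega, bls = unpack(x)
        for node, bl in zip(branches, bls):
            node.length = float(bl)
        return -engine.log_likelihood(kappa, [(1.0, omega)])

    tracker = _BestTracker(objective)
    bounds = (
        [tuple(np.log(KAPPA_BOUNDS)), tuple(np.log(OMEGA_BOUNDS))]
        + [tuple(np.log(BRANCH_BOUNDS))] * nb
    )
    bl0 = np.log([max(b.length, 1e-4) for b in branches])
    converged = False
    for kappa0, omega0 in _M0_STARTS[:n_starts]:
        x0 = np.concatenate([[math.log(kappa0), math.log(omega0)], bl0])
        ok = _minimize(tracker, x0, bounds)
        converged = converged or ok
    kappa, omega, bls = unpack(tracker.best_x)
    for node, bl in zip(branches, bls):
        node.length = float(bl)
    lnl, site_matrix = engine.log_likelihood(
        kappa, [(1.0, omega)], return_site_matrix=True
    )
    fit = SiteModelFit(
        model="M0", kappa=kappa, params={"omega": omega}, lnl=lnl,
        tree=work_tree, branch_scale=1.0, categories=[(1.0, omega)],
        site_posteriors=np.ones((aln.n_sites, 1)), converged=converged,
    )
    if work_tree.total_length() < 1e-4:
        fit.flags.append("omega_unidentifiable_zero_tree_length")
    if not converged:
        fit.flags.append("optimizer_not_converged")
    return fit


def _stick_to_weights(a: float, b: float) -> tuple[float, float, float]:
    return a, (1 - a) * b, (1 - a) * (1 - b)


def _fit_mixture(aln, model, codon_freqs, null_fit) -> SiteModelFit:
    work_tree = copy.deepcopy(null_fit.tree)
    engine = CodonLikelihood(aln, work_tree, codon_freqs)
    log = math.log
    lb, ub = {}, {}

    if model == "M3":
        # x = [log kappa, log scale, stick a, stick b, log w0, log w1, log w2]
        def categories_of(x):
            a, b = x[2], x[3]
            weights = _stick_to_weights(a, b)
            omegas = np.exp(x[4:7])
            return list(zip(weights, omegas))

        w0 = null_fit.params["omega"]
        x0s = [
            np.array([log(null_fit.kappa), 0.0, 1 / 3, 0.5,
                      log(w0), log(w0), log(w0)]),
            np.array([log(null_fit.kappa), 0.0, 1 / 3, 0.5,
                      log(max(w0 / 4, 1e-4)), log(w0), log(min(w0 * 4, 40.0))]),
        ]
        bounds = [
            tuple(np.log(KAPPA_BOUNDS)), tuple(np.log(SCALE_BOUNDS)),
            (1e-4, 1 - 1e-4), (1e-4, 1 - 1e-4),
        ] + [tuple(np.log(OMEGA_BOUNDS))] * 3
    elif model == "M7":
        def categories_of(x):
            return model_categories("M7", {"p": math.exp(x[2]), "q": math.exp(x[3])})

        x0s = [
            np.array([log(null_fit.kappa), 0.0, log(0.5), log(1.5)]),
            np.array([log(null_fit.kappa), 0.0, log(2.0), log(5.0)]),
            np.array([log(null_fit.kappa), 0.0, log(1.0), log(1.0)]),
        ]
        bounds = [
            tuple(np.log(KAPPA_BOUNDS)), tuple(np.log(SCALE_BOUNDS)),
            tuple(np.log(BETA_BOUNDS)), tuple(np.log(BETA_BOUNDS)),
        ]
    elif model == "M8":
        # x = [log kappa, log scale, log p, log q, p0, log omega_s]
        def categories_of(x):
            return model_categories(
                "M8",
                {"p": math.exp(x[2]), "q": math.exp(x[3]),
                 "p0": x[4], "omega_s": math.exp(x[5])},
            )

        k7 = log(null_fit.kappa)
        s7 = log(null_fit.branch_scale)
        p7, q7 = log(null_fit.params["p"]), log(null_fit.params["q"])
        x0s = [
            np.array([k7, s7, p7, q7, 1.0, log(2.0)]),       # exactly M7
            np.array([k7, s7, p7, q7, 0.9, log(2.0)]),
            np.array([k7, s7, p7, q7, 0.7, log(4.0)]),
        ]
        bounds = [
            tuple(np.log(KAPPA_BOUNDS)), tuple(np.log(SCALE_BOUNDS)),
            tuple(np.log(BETA_BOUNDS)), tuple(np.log(BETA_BOUNDS)),
            (1e-6, 1.0), (0.0, log(OMEGA_BOUNDS[1])),        # omega_s >= 1
        ]
    else:  # pragma: no cover
        raise ValueError(model)

    def objective(x):
        kappa = math.exp(x[0])
        scale = math.exp(x[1])
        return -engine.log_likelihood(kappa, categories_of(x), scale)

    tracker = _BestTracker(objective)
    converged = False
    for x0 in x0s:
        converged = _minimize(tracker, x0, bounds) or converged
    x = tracker.best_x
    kappa, scale = math.exp(x[0]), math.exp(x[1])
    cats = categories_of(x)
    lnl, site_matrix = engine.log_likelihood(
        kappa, cats, scale, return_site_matrix=True
    )
    if model == "M3":
        a, b = x[2], x[3]
        params = {
            "weights": list(_stick_to_weights(a, b)),
            "omegas": [float(v) for v in np.exp(x[4:7])],
        }
    elif model == "M7":
        params = {"p": math.exp(x[2]), "q": math.exp(x[3])}
    else:
        params = {
            "p": math.exp(x[2]), "q": math.exp(x[3]),
            "p0": float(x[4]), "omega_s": math.exp(x[5]),
        }
    posteriors = _neb_posteriors(cats, site_matrix)
    fit = SiteModelFit(
        model=model, kappa=kappa, params=params, lnl=lnl, tree=work_tree,
        branch_scale=scale, categories=cats, site_posteriors=posteriors,
        converged=converged,
    )
    if not converged:
        fit.flags.append("optimizer_not_converged")
    return fit


def _neb_posteriors(categories, site_matrix: np.ndarray) -> np.ndarray:
    """Naive empirical Bayes class posteriors per site (nsites, ncats)."""
    weights = np.array([w for w, _ in categories])[:, None]
    logjoint = np.log(np.maximum(weights, 1e-300)) + site_matrix
    m = logjoint.max(axis=0, keepdims=True)
    joint = np.exp(logjoint - m)
    return (joint / joint.sum(axis=0, keepdims=True)).T


def lrt(fit_null: SiteModelFit, fit_alt: SiteModelFit,
        df: Optional[int] = None) -> LrtResult:
    """2*(lnL_alt - lnL_null) against chi-square.

    Only the nested pairs M0/M3 (df 4) and M7/M8 (df 2) are accepted; a
    slightly negative statistic (optimizer tolerance) is clamped to zero.
    """
    pair = (fit_null.model, fit_alt.model)
    if pair not in _NESTED_PAIRS:
        raise ValueError(f"models {pair} are not a supported nested pair")
    expected_df = _NESTED_PAIRS[pair]
    if df is not None and df != expected_df:
        raise ValueError(f"df for {pair} must be {expected_df}")
    stat = 2.0 * (fit_alt.lnl - fit_null.lnl)
    if stat < 0:
        if stat < -1e-3:
            raise ValueError(
                f"alternative fit worse than null by {-stat / 2:.6g} lnL units; "
                "refit before testing"
            )
        stat = 0.0
    p = float(stats.chi2.sf(stat, expected_df)) if stat > 0 else 1.0
    return LrtResult(fit_null.model, fit_alt.model, stat, expected_df, p)


def positive_sites(fit: SiteModelFit, threshold: float = 0.95) -> list[int]:
    """NEB positively selected sites: posterior mass on omega > 1 classes
    above ``threshold``.  Returns 0-based site indices."""
    if fit.site_posteriors is None:
        raise ValueError("fit carries no site posteriors")
    pos_classes = np.array([om > 1.0 for _, om in fit.categories])
    if not pos_classes.any():
        return []
    mass = fit.site_posteriors[:, pos_classes].sum(axis=1)
    return [int(i) for i in np.nonzero(mass > threshold)[0]]


def significance_stars(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def selection_report(
    datasets: Sequence[dict],
) -> pd.DataFrame:
    """Tabulate per-dataset site-model results.

    Each entry: ``{"name": str, "fits": {model: SiteModelFit},
    "lrts": {"M0_M3": LrtResult, "M7_M8": LrtResult}}``.  Columns mirror the
    conventional report: omega under M0, the two LRT statistics with
    significance stars, the M8 estimates and the NEB positive-site count.
    """
    rows = []
    for entry in datasets:
        fits = entry["fits"]
        lrts = entry.get("lrts", {})
        m8 = fits.get("M8")
        row = {"dataset": entry["name"]}
        if "M0" in fits:
            row["omega_M0"] = fits["M0"].params["omega"]
        for key, label in (("M0_M3", "2dlnL_M3_vs_M0"), ("M7_M8", "2dlnL_M8_vs_M7")):
            res = lrts.get(key)
            if res is not None:
                row[label] = res.stat
                row[label + "_sig"] = significance_stars(res.p_value)
        if m8 is not None:
            row["M8_omega_s"] = m8.params["omega_s"]
            row["M8_p"] = m8.params["p"]
            row["M8_q"] = m8.params["q"]
            row["M8_p0"] = m8.params["p0"]
            row["n_positive_sites"] = len(positive_sites(m8))
        rows.append(row)
    return pd.DataFrame(rows)
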