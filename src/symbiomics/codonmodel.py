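"""GY94-style codon substitution model with discrete-omega site classes.

The engine provides:

* a reversible Goldman-Yang rate matrix over the 61 sense codons with
  transition/transversion ratio kappa, per-class omega, and F3x4 codon
  frequencies estimated from the data;
* Felsenstein pruning over an input tree whose branch lengths are rescaled
  by one free multiplier (full branch-length optimization is deliberately
  omitted);
* maximum-likelihood fits of the M7 (omega ~ Beta(p, q), 10 categories)
  and M8 (proportion p0 from the beta plus p1 = 1 - p0 at omega_s > 1,
  11 categories) site models, with NEB per-site class posteriors;
* a sampler that draws alignments from exactly this process, used for
  power and type-I calibration studies.

Because one global rate multiplier is a free parameter, the rate matrix is
left unnormalized: only relative rates between site classes matter.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import logsumexp

from .codons import CODON_INDEX, SENSE_CODONS, is_synonymous, is_transition
from .selection import discretize_beta

N_CODONS = len(SENSE_CODONS)  # 61

# Sparse structure of single-nucleotide codon exchanges, built once:
# index pairs plus transition / nonsynonymous indicator vectors.
_PAIR_I: list[int] = []
_PAIR_J: list[int] = []
_PAIR_TS: list[bool] = []
_PAIR_NONSYN: list[bool] = []
for _i, _ci in enumerate(SENSE_CODONS):
    for _j, _cj in enumerate(SENSE_CODONS):
        if _i == _j:
            continue
        diffs = [(a, b) for a, b in zip(_ci, _cj) if a != b]
        if len(diffs) != 1:
            continue
        _PAIR_I.append(_i)
        _PAIR_J.append(_j)
        _PAIR_TS.append(is_transition(*diffs[0]))
        _PAIR_NONSYN.append(not is_synonymous(_ci, _cj))
PAIR_I = np.array(_PAIR_I)
PAIR_J = np.array(_PAIR_J)
PAIR_TS = np.array(_PAIR_TS)
PAIR_NONSYN = np.array(_PAIR_NONSYN)


def f3x4_frequencies(codon_matrix: np.ndarray) -> np.ndarray:
    """F3x4 codon frequencies from observed position-specific nucleotide counts.

    ``codon_matrix`` holds codon indices (values in 0..60); -1 entries are
    ignored.  Returns frequencies over the 61 sense codons (normalized).
    """
    pos_counts = np.ones((3, 4))  # +1 pseudocount keeps frequencies positive
    nuc_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    flat = codon_matrix[codon_matrix >= 0].ravel()
    for idx in flat:
        codon = SENSE_CODONS[idx]
        for pos in range(3):
            pos_counts[pos, nuc_index[codon[pos]]] += 1
    pos_freq = pos_counts / pos_counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            pos_freq[0, nuc_index[c[0]]] * pos_freq[1, nuc_index[c[1]]] * pos_freq[2, nuc_index[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    return pi / pi.sum()


def rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """Unnormalized GY94 rate matrix Q for one omega class."""
    rates = np.where(PAIR_TS, kappa, 1.0) * np.where(PAIR_NONSYN, omega, 1.0)
    q = np.zeros((N_CODONS, N_CODONS))
    q[PAIR_I, PAIR_J] = rates * pi[PAIR_J]
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


class _Eigendecomposition:
    """Symmetric eigendecomposition of a reversible Q for fast P(t).

    With D = diag(pi), B = D^{1/2} Q D^{-1/2} is symmetric for a
    reversible Q; then P(t) = D^{-1/2} U exp(L t) U^T D^{1/2}.
    """

    def __init__(self, kappa: float, omega: float, pi: np.ndarray):
        sqrt_pi = np.sqrt(pi)
        q = rate_matrix(kappa, omega, pi)
        b = (q / sqrt_pi[None, :]) * sqrt_pi[:, None]
        self.eigval, u = np.linalg.eigh(b)
        self.left = u / sqrt_pi[:, None]       # D^{-1/2} U
        self.right = (u * sqrt_pi[:, None]).T  # U^T D^{1/2}

    def transition_matrix(self, t: float) -> np.ndarray:
        p = (self.left * np.exp(self.eigval * t)) @ self.right
        np.clip(p, 0.0, None, out=p)
        return p


class _BatchedEigen:
    """Eigendecompositions for all omega categories at once (batched LAPACK)."""

    def __init__(self, kappa: float, omegas: np.ndarray, pi: np.ndarray):
        sqrt_pi = np.sqrt(pi)
        base = np.where(PAIR_TS, kappa, 1.0)
        qs = np.zeros((len(omegas), N_CODONS, N_CODONS))
        for ci, w in enumerate(omegas):
            rates = base * np.where(PAIR_NONSYN, w, 1.0)
            qs[ci, PAIR_I, PAIR_J] = rates * pi[PAIR_J]
            qs[ci, np.arange(N_CODONS), np.arange(N_CODONS)] = -qs[ci].sum(axis=1)
        b = (qs / sqrt_pi[None, None, :]) * sqrt_pi[None, :, None]
        self.eigval, u = np.linalg.eigh(b)
        self.left = u / sqrt_pi[None, :, None]
        self.right = np.swapaxes(u * sqrt_pi[None, :, None], 1, 2)

    def transition_matrices(self, t: float) -> np.ndarray:
        """(ncat, 61, 61) transition matrices for one branch length."""
        p = np.matmul(self.left * np.exp(self.eigval * t)[:, None, :], self.right)
        np.clip(p, 0.0, None, out=p)
        return p


def _model_classes(model: str, params: dict[str, float], ncat_beta: int = 10):
    """Category omega rates and weights for M7 / M8."""
    rates, weights = discretize_beta(params["p"], params["q"], ncat_beta)
    if model == "M7":
        return rates, weights
    if model == "M8":
        p0 = params["p0"]
        rates = np.append(rates, params["omega_s"])
        weights = np.append(weights * p0, 1.0 - p0)
        return rates, weights
    raise ValueError(f"unknown model {model!r}")


class _TreeData:
    """Flattened postorder view of a Bio.Phylo tree for pruning."""

    def __init__(self, tree, taxa: list[str]):
        self.taxon_row = {name: i for i, name in enumerate(taxa)}
        self.postorder: list[tuple[int, list[tuple[int, float]]]] = []
        ids: dict[int, int] = {}
        counter = itertools.count()

        def walk(clade):
            my_id = next(counter)
            ids[id(clade)] = my_id
            if clade.is_terminal():
                if clade.name not in self.taxon_row:
                    raise ValueError(f"tree tip {clade.name!r} missing from alignment")
                self.tip_of[my_id] = self.taxon_row[clade.name]
                return my_id
            children = []
            for child in clade.clades:
                cid = walk(child)
                bl = child.branch_length
                if bl is None or bl < 0:
                    raise ValueError("tree must have nonnegative branch lengths")
                children.append((cid, float(bl)))
            self.postorder.append((my_id, children))
            return my_id

        self.tip_of: dict[int, int] = {}
        self.root = walk(tree.root)
        self.n_nodes = next(counter)
        self.branch_lengths = sorted(
            {bl for _, children in self.postorder for _, bl in children}
        )


def _site_log_likelihoods(
    tree_data: _TreeData,
    patterns: np.ndarray,  # (n_taxa, npat) codon indices
    pi: np.ndarray,
    kappa: float,
    scaler: float,
    rates: np.ndarray,
    weights: np.ndarray,
) -> np.ndarray:
    """Per-pattern, per-class weighted log-likelihoods, shape (ncat, npat).

    All omega categories are pruned simultaneously with batched matrix
    products; tip contributions use the one-hot shortcut (a row gather
    from P instead of a matmul).
    """
    npat = patterns.shape[1]
    ncat = len(rates)
    eig = _eigen_cached(kappa, rates, pi)
    # transposed transition matrices per unique branch length
    pts = {bl: np.ascontiguousarray(np.swapaxes(eig.transition_matrices(bl * scaler), 1, 2))
           for bl in tree_data.branch_lengths}
    partial: dict[int, np.ndarray] = {}
    logscale = np.zeros((ncat, npat))
    for node_id, children in tree_data.postorder:
        acc = np.ones((ncat, npat, N_CODONS))
        for child_id, bl in children:
            pt = pts[bl]
            if child_id in tree_data.tip_of:
                states = patterns[tree_data.tip_of[child_id]]
                contrib = pt[:, states, :]  # (ncat, npat, 61), one-hot gather
            else:
                contrib = np.matmul(partial.pop(child_id), pt)
            acc *= contrib
        mx = acc.max(axis=2)
        mx[mx == 0.0] = 1.0
        acc /= mx[:, :, None]
        logscale += np.log(mx)
        partial[node_id] = acc
    root_lik = partial[tree_data.root] @ pi
    return np.log(np.maximum(root_lik, 1e-300)) + logscale + np.log(weights)[:, None]


_EIG_CACHE: dict[tuple, _BatchedEigen] = {}


def _eigen_cached(kappa: float, rates: np.ndarray, pi: np.ndarray) -> _BatchedEigen:
    """Memoize eigendecompositions: optimizer steps that vary only the
    branch-length scaler reuse the previous decomposition."""
    key = (float(kappa), rates.tobytes(), pi.tobytes())
    hit = _EIG_CACHE.get(key)
    if hit is None:
        if len(_EIG_CACHE) > 64:
            _EIG_CACHE.clear()
        hit = _EIG_CACHE[key] = _BatchedEigen(kappa, rates, pi)
    return hit


@dataclass
class SiteModelFit:
    """Maximum-likelihood fit of one codon site model."""

    model: str
    params: dict[str, float]
    lnl: float
    rates: np.ndarray
    weights: np.ndarray
    site_posteriors: np.ndarray  # (n_sites, ncat)
    converged: bool
    data_hash: str
    n_free_params: int


def encode_alignment(sequences: dict[str, str]) -> tuple[list[str], np.ndarray, list[int]]:
    """Codon-index matrix from aligned nucleotide sequences.

    Codon columns containing gaps, ambiguity codes or stops in any sequence
    are dropped; the returned list of kept codon-column indices (0-based)
    maps matrix columns back to alignment positions.
    """
    taxa = list(sequences)
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must have equal length")
    (length,) = lengths
    if length % 3:
        raise ValueError("alignment length must be a multiple of 3")
    cols = []
    kept = []
    for c in range(length // 3):
        codons = [sequences[t][3 * c : 3 * c + 3].upper() for t in taxa]
        if all(cd in CODON_INDEX for cd in codons):
            cols.append([CODON_INDEX[cd] for cd in codons])
            kept.append(c)
    if not cols:
        raise ValueError("no usable codon columns in alignment")
    return taxa, np.array(cols).T, kept


def _compress_patterns(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    patterns, inverse, counts = np.unique(matrix, axis=1, return_inverse=True, return_counts=True)
    return patterns, inverse, counts.astype(float)


def _pack_m7(x):
    return {"p": np.exp(x[0]), "q": np.exp(x[1]), "kappa": np.exp(x[2]), "scaler": np.exp(x[3])}


def _pack_m8(x):
    d = _pack_m7(x)
    d["p0"] = 1.0 / (1.0 + np.exp(-x[4]))
    d["omega_s"] = 1.0 + np.exp(x[5])
    return d


_LOG_BOUNDS = (np.log(0.02), np.log(50.0))
_M7_BOUNDS = [_LOG_BOUNDS, _LOG_BOUNDS, (np.log(0.2), np.log(20.0)), (np.log(1e-6), np.log(50.0))]
# wide p0 bounds let M8 collapse numerically onto M7 (p0 -> 1), which keeps
# the nesting property lnL(M8) >= lnL(M7) to ~1e-8 even at finite bounds
_M8_BOUNDS = _M7_BOUNDS + [(-25.0, 25.0), (np.log(1e-6), np.log(49.0))]


def fit_site_model(
    sequences: dict[str, str],
    tree,
    model: str,
    ncat_beta: int = 10,
    n_starts: int = 3,
    seed: int = 0,
    maxfun: int = 250,
    maxiter: int = 60,
    init: dict[str, float] | None = None,
    base_start: bool = True,
) -> SiteModelFit:
    """Fit M7 or M8 by maximizing the pruning likelihood.

    ``n_starts`` random restarts (seeded) are run in addition to a default
    start (and, for M8, any caller-supplied ``init`` — typically the M7
    optimum).  The best optimum is returned; ``converged`` is False only if
    every start failed outright, in which case the best evaluated point is
    still attached.
    """
    if model not in ("M7", "M8"):
        raise ValueError(f"model must be 'M7' or 'M8', got {model!r}")
    taxa, matrix, kept = encode_alignment(sequences)
    if len(taxa) < 2:
        raise ValueError("need at least 2 sequences")
    patterns, inverse, counts = _compress_patterns(matrix)
    pi = f3x4_frequencies(matrix)
    tree_data = _TreeData(tree, taxa)

    pack = _pack_m7 if model == "M7" else _pack_m8
    bounds = _M7_BOUNDS if model == "M7" else _M8_BOUNDS

    def neg_lnl(x):
        prm = pack(x)
        rates, weights = _model_classes(model, prm, ncat_beta)
        ll = _site_log_likelihoods(tree_data, patterns, pi, prm["kappa"], prm["scaler"], rates, weights)
        return -float(np.dot(counts, logsumexp(ll, axis=0)))

    rng = np.random.default_rng(seed)
    starts = []
    if init is None or base_start:
        base = [np.log(0.5), np.log(1.5), np.log(2.0), np.log(0.5)]
        if model == "M8":
            base = base + [np.log(0.9 / 0.1), np.log(1.0)]  # p0=0.9, omega_s=2
        starts.append(np.array(base))
    if init is not None:
        x0 = [np.log(init["p"]), np.log(init["q"]), np.log(init["kappa"]), np.log(init["scaler"])]
        if model == "M8":
            p0 = min(max(init.get("p0", 0.9), 1e-4), 1 - 1e-4)
            ws = max(init.get("omega_s", 2.0), 1.0 + 1e-6)
            x0 += [np.log(p0 / (1 - p0)), np.log(ws - 1.0)]
        starts.append(np.array(x0))
    for _ in range(n_starts):
        x0 = np.array([rng.uniform(lo, hi) for lo, hi in bounds])
        starts.append(x0)

    best = None
    if model == "M8" and init is not None and "p0" not in init:
        # candidate embedding the M7 optimum at the p0 boundary: guarantees
        # the nested model is never reported below its special case
        x_embed = np.array(
            [np.log(init["p"]), np.log(init["q"]), np.log(init["kappa"]),
             np.log(init["scaler"]), _M8_BOUNDS[4][1], _M8_BOUNDS[5][0]]
        )
        best = optimize.OptimizeResult(x=x_embed, fun=neg_lnl(x_embed), success=False)
    any_success = False
    for x0 in starts:
        res = optimize.minimize(
            neg_lnl,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxfun": maxfun, "maxiter": maxiter, "ftol": 1e-9},
        )
        any_success = any_success or res.success
        if best is None or res.fun < best.fun:
            best = res
    prm = pack(best.x)
    rates, weights = _model_classes(model, prm, ncat_beta)
    ll = _site_log_likelihoods(tree_data, patterns, pi, prm["kappa"], prm["scaler"], rates, weights)
    # NEB posteriors per site (expand pattern -> site)
    log_post = ll - logsumexp(ll, axis=0, keepdims=True)
    posteriors = np.exp(log_post).T[inverse]  # (n_sites, ncat)
    digest = hashlib.sha256(matrix.tobytes() + ",".join(taxa).encode()).hexdigest()
    n_free = 4 if model == "M7" else 6  # counting kappa and the rate scaler
    return SiteModelFit(
        model=model,
        params={k: float(v) for k, v in prm.items()},
        lnl=-float(best.fun),
        rates=rates,
        weights=weights,
        site_posteriors=posteriors,
        converged=bool(any_success),
        data_hash=digest,
        n_free_params=n_free,
    )


def pairwise_lnl(seq_a: str, seq_b: str, t: float, kappa: float, omega: float, pi: np.ndarray) -> float:
    """Direct two-sequence log-likelihood sum_i log(pi_i * P(t)_{i j}).

    Independent closed-form route used to validate the pruning engine on
    two-taxon trees with a single omega class.
    """
    _, matrix, _ = encode_alignment({"a": seq_a, "b": seq_b})
    eig = _Eigendecomposition(kappa, omega, pi)
    p = eig.transition_matrix(t)
    vals = pi[matrix[0]] * p[matrix[0], matrix[1]]
    return float(np.log(vals).sum())


def simulate_site_model(
    tree,
    n_codons: int,
    model: str,
    params: dict[str, float],
    rng: np.random.Generator,
    pi: np.ndarray | None = None,
    ncat_beta: int = 10,
) -> tuple[dict[str, str], np.ndarray]:
    """Sample an in-frame alignment from the M7/M8 process on a tree.

    Per-site omega classes are drawn from the model's discrete mixture
    (matching the fitted likelihood exactly), the root codon from ``pi``
    (uniform over sense codons when None), and each branch transition from
    the matrix exponential of the class's rate matrix.  Returns the tip
    sequences and the true per-site class indices.
    """
    if pi is None:
        pi = np.full(N_CODONS, 1.0 / N_CODONS)
    rates, weights = _model_classes(model, params, ncat_beta)
    site_class = rng.choice(len(rates), size=n_codons, p=weights / weights.sum())
    kappa = params["kappa"]
    scaler = params.get("scaler", 1.0)
    # normalize so branch lengths are expected substitutions per codon
    # under the mixture-averaged rate
    mean_rate = -sum(
        w * float(np.dot(pi, np.diag(rate_matrix(kappa, om, pi))))
        for om, w in zip(rates, weights / weights.sum())
    )
    scaler = scaler / mean_rate

    eigs = [_Eigendecomposition(kappa, w, pi) for w in rates]
    root_states = rng.choice(N_CODONS, size=n_codons, p=pi)
    tip_states: dict[str, np.ndarray] = {}

    def evolve(clade, states):
        for child in clade.clades:
            t = float(child.branch_length) * scaler
            child_states = states.copy()
            for ci in np.unique(site_class):
                mask = site_class == ci
                pmat = eigs[ci].transition_matrix(t)
                cum = np.cumsum(pmat, axis=1)
                u = rng.random(mask.sum())
                rows = cum[states[mask]]
                child_states[mask] = (rows < u[:, None]).sum(axis=1)
            if child.is_terminal():
                tip_states[child.name] = child_states
            else:
                evolve(child, child_states)

    evolve(tree.root, root_states)
    seqs = {
        name: "".join(SENSE_CODONS[s] for s in states) for name, states in tip_states.items()
    }
    return seqs, site_class
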