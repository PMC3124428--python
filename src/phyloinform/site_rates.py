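"""Per-site substitution-rate estimation on a fixed ultrametric tree.

Each alignment column gets an independent maximum-likelihood rate: branch
lengths are multiplied by a candidate rate ``lambda``, the column likelihood
is computed by Felsenstein pruning under a time-reversible model, and
``lambda`` is optimized by golden-section search on ``[0, lambda_max]``.

Models: JC69 (DNA default), K80, HKY85, GTR, and POISSON20 (equal-rates
20-state, protein default).  Generators are scaled so one unit of
``lambda * time`` equals one expected substitution per site.

Implementation notes: the pruning recursion is vectorized across columns
(one golden-section search advances all columns of a locus in lockstep),
with per-node rescaling to avoid underflow at high rates.  All per-column
arithmetic is elementwise, so results are bitwise identical whether columns
are processed in one batch, per unique column (the cache), or singly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .io_phylo import (
    Alignment,
    UltrametricTree,
    SiteRateVector,
    ValidationError,
    DNA_STATES,
    PROTEIN_STATES,
    state_set,
    is_missing,
)

__all__ = [
    "SubstitutionModel",
    "RateEstimate",
    "make_model",
    "fit_model",
    "site_likelihood",
    "estimate_site_rate",
    "estimate_locus_rates",
    "locus_summary",
]

_GOLDEN_ITERS = 72  # shrinks [0, lambda_max] below 1e-14 * lambda_max
_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0

# DNA exchangeability order over states A,C,G,T
_DNA_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]  # AC AG AT CG CT GT
_TRANSITIONS = {(0, 2), (1, 3)}  # A<->G, C<->T


@dataclass(frozen=True)
class SubstitutionModel:
    """A normalized time-reversible rate matrix with its spectral form.

    ``Q`` satisfies detailed balance pi_i Q_ij = pi_j Q_ji and is scaled so
    -sum(pi_i Q_ii) = 1: ``lambda`` is then in expected substitutions per
    site per unit of tree time.
    """

    name: str
    alphabet: str  # "DNA" | "PROTEIN"
    pi: np.ndarray
    Q: np.ndarray
    _eigvals: np.ndarray = field(repr=False, default=None)
    _right: np.ndarray = field(repr=False, default=None)  # D^-1/2 V
    _left: np.ndarray = field(repr=False, default=None)   # V^T D^1/2

    @property
    def n_states(self) -> int:
        return self.pi.size

    @property
    def states(self) -> str:
        return DNA_STATES if self.alphabet == "DNA" else PROTEIN_STATES

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Q t) via the symmetric eigendecomposition."""
        if t < 0:
            raise ValueError("time must be non-negative")
        if t == 0:
            return np.eye(self.n_states)
        e = np.exp(self._eigvals * t)
        P = (self._right * e) @ self._left
        return np.clip(P, 0.0, None)


def _build_reversible(name: str, alphabet: str, pi: np.ndarray,
                      rates_sym: np.ndarray) -> SubstitutionModel:
    """Assemble, normalize, and spectrally decompose Q_ij = s_ij * pi_j."""
    pi = np.asarray(pi, dtype=float)
    pi = pi / pi.sum()
    if np.any(pi <= 0):
        raise ValidationError(f"model {name}: frequencies must be positive")
    Q = rates_sym * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    beta = -float(np.sum(pi * np.diag(Q)))
    Q = Q / beta
    # symmetrize: B = D^1/2 Q D^-1/2 with D = diag(pi)
    sq = np.sqrt(pi)
    B = (sq[:, None] * Q) / sq[None, :]
    B = 0.5 * (B + B.T)
    w, V = np.linalg.eigh(B)
    right = V / sq[:, None]
    left = V.T * sq[None, :]
    return SubstitutionModel(name=name, alphabet=alphabet, pi=pi, Q=Q,
                             _eigvals=w, _right=right, _left=left)


def _dna_sym(exch6) -> np.ndarray:
    s = np.zeros((4, 4))
    for (i, j), v in zip(_DNA_PAIRS, exch6):
        if v < 0:
            raise ValidationError("exchangeabilities must be >= 0")
        s[i, j] = s[j, i] = v
    return s


def empirical_frequencies(alignment: Alignment) -> np.ndarray:
    """State frequencies from unambiguous symbol counts (+1 pseudocount)."""
    states = DNA_STATES if alignment.alphabet == "DNA" else PROTEIN_STATES
    counts = np.ones(len(states))
    for seq in alignment.sequences:
        up = seq.upper()
        for k, c in enumerate(states):
            counts[k] += up.count(c)
    return counts / counts.sum()


def make_model(name: str, frequencies=None, kappa: float = 2.0,
               exchangeabilities=None, alignment: Alignment | None = None
               ) -> SubstitutionModel:
    """Construct a substitution model by name.

    ``jc69`` and ``poisson20`` need no parameters.  ``k80`` takes
    ``kappa``; ``hky85`` and ``gtr`` take frequencies (explicit, or
    empirical from ``alignment``, default uniform) and ``gtr`` the six
    exchangeabilities (order AC, AG, AT, CG, CT, GT).
    """
    name = name.lower()
    if name == "poisson20":
        pi = np.full(20, 1 / 20)
        return _build_reversible("POISSON20", "PROTEIN", pi, np.ones((20, 20)))
    if name not in ("jc69", "k80", "hky85", "gtr"):
        raise ValidationError(f"unknown model {name!r}")
    if frequencies is None:
        if name in ("hky85", "gtr") and alignment is not None:
            frequencies = empirical_frequencies(alignment)
        else:
            frequencies = np.full(4, 0.25)
    if name == "jc69":
        return _build_reversible("JC69", "DNA", np.full(4, 0.25), np.ones((4, 4)))
    if name == "k80":
        ex = [kappa if (i, j) in _TRANSITIONS else 1.0 for i, j in _DNA_PAIRS]
        return _build_reversible("K80", "DNA", np.full(4, 0.25), _dna_sym(ex))
    if name == "hky85":
        ex = [kappa if (i, j) in _TRANSITIONS else 1.0 for i, j in _DNA_PAIRS]
        return _build_reversible("HKY85", "DNA", frequencies, _dna_sym(ex))
    if exchangeabilities is None:
        exchangeabilities = np.ones(6)
    return _build_reversible("GTR", "DNA", frequencies,
                             _dna_sym(np.asarray(exchangeabilities, dtype=float)))


def default_model(alphabet: str) -> SubstitutionModel:
    return make_model("jc69" if alphabet == "DNA" else "poisson20")


# ---------------------------------------------------------------------------
# tree compilation


class _TreeCache:
    """Postorder program for the pruning recursion.

    Tips occupy slots 0..n_tips-1 (in ``tip_labels`` order); internal nodes
    follow in postorder, the root last.
    """

    def __init__(self, utree: UltrametricTree):
        tree = utree.tree
        self.depth = utree.depth
        leaves = tree.leaf_nodes()
        self.tip_labels = [lf.taxon.label for lf in leaves]
        slot = {id(lf): k for k, lf in enumerate(leaves)}
        self.n_tips = len(leaves)
        self.ops: list[tuple[int, list[tuple[int, float]]]] = []
        nxt = self.n_tips
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                continue
            children = [
                (slot[id(ch)], float(ch.edge.length or 0.0))
                for ch in node.child_nodes()
            ]
            slot[id(node)] = nxt
            self.ops.append((nxt, children))
            nxt += 1
        self.n_nodes = nxt
        self.root_slot = slot[id(tree.seed_node)]


def _tip_partials(columns: list[dict[str, str]], cache: _TreeCache,
                  model: SubstitutionModel) -> np.ndarray:
    """(n_tips, n_cols, k) conditional likelihoods at the tips."""
    k = model.n_states
    out = np.zeros((cache.n_tips, len(columns), k))
    for c, col in enumerate(columns):
        for r, label in enumerate(cache.tip_labels):
            try:
                sym = col[label]
            except KeyError:
                raise ValidationError(f"taxon {label!r} missing from column")
            out[r, c, list(state_set(sym, model.alphabet))] = 1.0
    return out


def _rowwise_mat(X: np.ndarray, M: np.ndarray) -> np.ndarray:
    # X (n, k) times M (k, k) with a fixed summation order so results do not
    # depend on batch size (bitwise cache-on/off reproducibility)
    out = X[:, 0, None] * M[None, 0, :]
    for j in range(1, M.shape[0]):
        out = out + X[:, j, None] * M[None, j, :]
    return out


def _batch_loglik(cache: _TreeCache, model: SubstitutionModel,
                  tipL: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Pruning log-likelihood for every column at its own rate."""
    n_cols = tipL.shape[1]
    k = model.n_states
    partial = np.zeros((cache.n_nodes, n_cols, k))
    partial[: cache.n_tips] = tipL
    logscale = np.zeros(n_cols)
    w = model._eigvals
    right_t = model._right.T
    left_t = model._left.T
    for slot, children in cache.ops:
        acc = np.ones((n_cols, k))
        for ch_slot, blen in children:
            t = lambdas * blen
            e = np.exp(w[None, :] * t[:, None])
            tmp = _rowwise_mat(partial[ch_slot], left_t) * e
            contrib = _rowwise_mat(tmp, right_t)
            # exact identity transition where lambda * blen == 0
            zero = t == 0.0
            if np.any(zero):
                contrib = np.where(zero[:, None], partial[ch_slot], contrib)
            acc = acc * np.clip(contrib, 0.0, None)
        m = acc.max(axis=1)
        nz = m > 0
        acc[nz] = acc[nz] / m[nz, None]
        with np.errstate(divide="ignore"):
            logscale = logscale + np.where(nz, np.log(np.where(nz, m, 1.0)), -np.inf)
        partial[slot] = acc
    root = partial[cache.root_slot]
    lik = root[:, 0] * model.pi[0]
    for j in range(1, k):
        lik = lik + root[:, j] * model.pi[j]
    with np.errstate(divide="ignore"):
        return np.where(lik > 0, np.log(np.where(lik > 0, lik, 1.0)), -np.inf) + logscale


def site_likelihood(column: dict[str, str], tree: UltrametricTree,
                    model: SubstitutionModel, lam: float) -> float:
    """Log-likelihood of one alignment column at rate ``lam``.

    ``column`` maps each taxon label on the tree to its observed symbol
    (ambiguity codes become state sets; missing symbols contribute ones).
    Returns -inf at ``lam = 0`` for a column that varies among its
    non-missing states (no substitutions can explain it).
    """
    if lam < 0:
        raise ValueError("rate must be non-negative")
    cache = _TreeCache(tree)
    tipL = _tip_partials([column], cache, model)
    return float(_batch_loglik(cache, model, tipL, np.array([float(lam)]))[0])


# ---------------------------------------------------------------------------
# estimation


@dataclass
class RateEstimate:
    """One site's ML rate with its optimization status."""

    site: int  # 1-based
    lambda_hat: float  # NaN when FAULTY
    loglik: float
    status: str  # OK | INVARIANT_ZERO | CLAMPED_MAX | FAULTY


def _classify_column(col: dict[str, str], alphabet: str) -> str:
    """'faulty' (<2 informative taxa), 'invariant', or 'variable'."""
    observed = [s.upper() for s in col.values() if not is_missing(s, alphabet)]
    if len(observed) < 2:
        return "faulty"
    first = observed[0]
    plain = set(DNA_STATES if alphabet == "DNA" else PROTEIN_STATES)
    if first in plain and all(s == first for s in observed):
        return "invariant"
    return "variable"


def _golden_section_batch(f, lo: float, hi: float, n_cols: int):
    """Vectorized golden-section maximization on [lo, hi] for every column.

    ``f(lams)`` evaluates all columns at per-column rates.  Deterministic:
    a fixed iteration count shrinks the bracket far below any tolerance of
    interest (1e-6 relative).
    """
    a = np.full(n_cols, lo)
    b = np.full(n_cols, hi)
    x1 = b - _INVPHI * (b - a)
    x2 = a + _INVPHI * (b - a)
    f1 = f(x1)
    f2 = f(x2)
    for _ in range(_GOLDEN_ITERS):
        left = f1 >= f2  # keep [a, x2]
        b = np.where(left, x2, b)
        a = np.where(left, a, x1)
        x1_new = b - _INVPHI * (b - a)
        x2_new = a + _INVPHI * (b - a)
        # one new evaluation per column per iteration; the surviving interior
        # point inherits its value (left keep: new x2 is the old x1, and
        # vice versa on the right)
        x_eval = np.where(left, x1_new, x2_new)
        f_eval = f(x_eval)
        f1, f2 = np.where(left, f_eval, f2), np.where(left, f1, f_eval)
        x1, x2 = x1_new, x2_new
    xm = 0.5 * (a + b)
    return xm, f(xm)


def _estimate_columns(columns: list[dict[str, str]], cache: _TreeCache,
                      model: SubstitutionModel, lambda_max: float
                      ) -> list[RateEstimate]:
    """Estimate rates for a list of (possibly repeated) columns."""
    kinds = [_classify_column(c, model.alphabet) for c in columns]
    estimates: list[RateEstimate | None] = [None] * len(columns)
    var_idx = [i for i, kd in enumerate(kinds) if kd == "variable"]
    for i, kd in enumerate(kinds):
        if kd == "faulty":
            estimates[i] = RateEstimate(i + 1, np.nan, np.nan, "FAULTY")
        elif kd == "invariant":
            ll = _batch_loglik(cache, model,
                               _tip_partials([columns[i]], cache, model),
                               np.array([0.0]))[0]
            estimates[i] = RateEstimate(i + 1, 0.0, float(ll), "INVARIANT_ZERO")
    if var_idx:
        tipL = _tip_partials([columns[i] for i in var_idx], cache, model)

        def f(lams):
            return _batch_loglik(cache, model, tipL, lams)

        lam_hat, ll_hat = _golden_section_batch(f, 0.0, lambda_max, len(var_idx))
        # boundary maxima: the bound attains the optimum, either because the
        # bracket converged there or because the likelihood plateaus up to it
        ll_bound = f(np.full(len(var_idx), lambda_max))
        clamped = (lam_hat >= (1.0 - 1e-6) * lambda_max) | (
            ll_bound >= ll_hat - 1e-9 * (1.0 + np.abs(ll_hat))
        )
        lam_out = np.where(clamped, lambda_max, lam_hat)
        ll_out = np.where(clamped, ll_bound, ll_hat)
        for j, i in enumerate(var_idx):
            if not np.isfinite(ll_out[j]):
                estimates[i] = RateEstimate(i + 1, np.nan, np.nan, "FAULTY")
            else:
                estimates[i] = RateEstimate(
                    i + 1, float(lam_out[j]), float(ll_out[j]),
                    "CLAMPED_MAX" if clamped[j] else "OK",
                )
    return estimates


def default_lambda_max(depth: float) -> float:
    """20 expected substitutions per site over the tree height."""
    return 20.0 / depth


def estimate_site_rate(column: dict[str, str], tree: UltrametricTree,
                       model: SubstitutionModel,
                       lambda_max: float | None = None) -> RateEstimate:
    """ML rate for a single column on the tree.

    Columns with fewer than two non-missing observations are FAULTY;
    invariant columns return 0 without optimization; a maximum on the
    upper bound is clamped and flagged CLAMPED_MAX.
    """
    cache = _TreeCache(tree)
    if lambda_max is None:
        lambda_max = default_lambda_max(cache.depth)
    return _estimate_columns([column], cache, model, lambda_max)[0]


def estimate_locus_rates(alignment: Alignment, tree: UltrametricTree,
                         model: SubstitutionModel | None = None,
                         lambda_max: float | None = None,
                         use_cache: bool = True,
                         return_details: bool = False):
    """Column-wise ML rates for a whole locus.

    Identical columns are recognized by hashing and estimated once
    (``use_cache=False`` disables this; results are bitwise identical
    either way).  Returns a SiteRateVector, plus the per-site
    RateEstimate list when ``return_details`` is set.
    """
    if model is None:
        model = default_model(alignment.alphabet)
    if model.alphabet != alignment.alphabet:
        raise ValidationError(
            f"model {model.name} is for {model.alphabet}, alignment is "
            f"{alignment.alphabet}"
        )
    cache = _TreeCache(tree)
    missing = set(alignment.taxa) - set(cache.tip_labels)
    if missing:
        raise ValidationError(f"alignment taxa absent from tree: {sorted(missing)}")
    if lambda_max is None:
        lambda_max = default_lambda_max(cache.depth)
    L = alignment.length
    columns = [alignment.column(i) for i in range(1, L + 1)]
    keys = [tuple(col[t] for t in cache.tip_labels) for col in columns]
    if use_cache:
        uniq: dict[tuple, int] = {}
        rep_idx: list[int] = []
        for i, key in enumerate(keys):
            if key not in uniq:
                uniq[key] = len(rep_idx)
                rep_idx.append(i)
        rep_est = _estimate_columns([columns[i] for i in rep_idx], cache,
                                    model, lambda_max)
        details = []
        for i, key in enumerate(keys):
            e = rep_est[uniq[key]]
            details.append(RateEstimate(i + 1, e.lambda_hat, e.loglik, e.status))
    else:
        details = []
        for i, col in enumerate(columns):
            e = _estimate_columns([col], cache, model, lambda_max)[0]
            details.append(RateEstimate(i + 1, e.lambda_hat, e.loglik, e.status))
    rates = np.array([d.lambda_hat for d in details])
    faulty = np.array([d.status == "FAULTY" for d in details])
    vector = SiteRateVector(
        locus_name=alignment.locus_name,
        rates=rates,
        faulty=faulty,
        model_tag=f"ml-{model.name}",
    )
    return (vector, details) if return_details else vector


def locus_summary(vector: SiteRateVector) -> dict:
    """The per-locus report row: length, rated sites, faulty sites, model."""
    return {
        "locus": vector.locus_name,
        "model": vector.model_tag,
        "length": vector.length,
        "n_rates": vector.n_estimated,
        "n_faulty": vector.n_faulty,
    }


# ---------------------------------------------------------------------------
# optional global model fitting (HKY85/GTR parameters shared across sites)


def fit_model(name: str, alignment: Alignment, tree: UltrametricTree,
              ) -> SubstitutionModel:
    """Fit K80/HKY85/GTR shape parameters globally on the variable sites.

    Base frequencies are empirical counts; kappa (K80/HKY85) or the five
    free exchangeabilities (GTR, GT fixed at 1) maximize the summed column
    log-likelihood at a shared rate of 1.  JC69/POISSON20 have nothing to
    fit and are returned directly.
    """
    name = name.lower()
    if name in ("jc69", "poisson20"):
        return make_model(name)
    freqs = empirical_frequencies(alignment)
    cache = _TreeCache(tree)
    columns = [alignment.column(i) for i in range(1, alignment.length + 1)]
    columns = [c for c in columns
               if _classify_column(c, alignment.alphabet) == "variable"]
    if not columns:
        return make_model(name, frequencies=freqs)
    # weight unique columns by multiplicity
    keys: dict[tuple, int] = {}
    uniq_cols = []
    weights = []
    for col in columns:
        key = tuple(col[t] for t in cache.tip_labels)
        if key in keys:
            weights[keys[key]] += 1
        else:
            keys[key] = len(uniq_cols)
            uniq_cols.append(col)
            weights.append(1)
    wts = np.array(weights, dtype=float)
    n_par = 1 if name in ("k80", "hky85") else 5

    def build(theta):
        vals = np.exp(theta)
        if name in ("k80", "hky85"):
            return make_model(name, frequencies=freqs, kappa=float(vals[0]))
        ex = np.append(vals, 1.0)  # AC AG AT CG CT, GT=1
        return make_model("gtr", frequencies=freqs, exchangeabilities=ex)

    def objective(theta):
        model = build(theta)
        tipL = _tip_partials(uniq_cols, cache, model)
        ll = _batch_loglik(cache, model, tipL, np.ones(len(uniq_cols)))
        return -float(np.sum(wts * ll))

    res = minimize(objective, np.zeros(n_par), method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 2000})
    return build(res.x)
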