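"""Substitution models: GTR+I+G for unpaired sites and the two paired-site
(base-pair) models used for stem columns.

The 7-state model treats the six canonical pairs A:U, U:A, G:C, C:G, G:U,
U:G as distinct states and lumps every other dinucleotide into one mismatch
state MM; it is the most general reversible model on those 7 states (21
exchangeabilities, 7 frequencies; 26 free parameters after removing the
rate scale).  The simplified 16-state model keeps all ordered dinucleotides
but collapses the exchangeabilities into five rate classes: single
substitutions, double substitutions and double transversions among the six
canonical states, single mutations between a canonical state and a mismatch
state, and single mutations between mismatch states; double changes
involving a mismatch state are forbidden (19 free parameters).

All models are reversible with ``q_ij = s_ij * pi_j`` and are normalised to
one expected event per unit branch length.  Rate heterogeneity follows the
usual invariant-sites + discrete-gamma mixture.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist
from scipy.linalg import expm

NUC = "ACGU"
PURINES = {"A", "G"}
CANONICAL_PAIRS = ("AU", "UA", "GC", "CG", "GU", "UG")
PAIR7_STATES = CANONICAL_PAIRS + ("MM",)
PAIR16_STATES = tuple(a + b for a in NUC for b in NUC)
MISMATCH_PAIRS = tuple(s for s in PAIR16_STATES if s not in CANONICAL_PAIRS)


def is_transition(a: str, b: str) -> bool:
    return a != b and (a in PURINES) == (b in PURINES)


def _check_frequencies(freqs: np.ndarray) -> None:
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError(f"frequencies sum to {freqs.sum()!r}, not 1")
    if (freqs < 0).any():
        raise ValueError("negative frequency")


def _reversible_q(sym: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Generator from a symmetric exchangeability matrix and stationary
    frequencies, scaled to mean rate 1."""
    q = sym * freqs[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -(freqs * np.diag(q)).sum()
    if scale <= 0:
        raise ValueError("degenerate rate matrix")
    return q / scale


def discrete_gamma_rates(shape: float, ncat: int) -> np.ndarray:
    """Mean rates of ``ncat`` equal-probability gamma(shape, 1/shape) bins."""
    if ncat == 1:
        return np.ones(1)
    edges = gamma_dist.ppf(np.linspace(0, 1, ncat + 1), a=shape,
                           scale=1.0 / shape)
    # mean within [a,b] of Gamma(shape, 1/shape) via the incomplete gamma
    upper = gammainc(shape + 1, edges[1:] * shape)
    lower = gammainc(shape + 1, edges[:-1] * shape)
    rates = (upper - lower) * ncat
    return rates / rates.mean()


class _ReversibleModel:
    """Shared machinery: eigendecomposition under the pi-symmetrisation."""

    states: tuple
    freqs: np.ndarray

    def rate_matrix(self) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_states(self) -> int:
        return len(self.states)

    def _decomposition(self):
        if getattr(self, "_decomp", None) is None:
            q = self.rate_matrix()
            pi = self.freqs
            if (pi > 0).all():
                sq = np.sqrt(pi)
                b = (sq[:, None] * q) / sq[None, :]
                b = (b + b.T) / 2.0
                w, v = np.linalg.eigh(b)
                u = v / sq[:, None]           # right eigenvectors of Q
                uinv = v.T * sq[None, :]      # inverse
                self._decomp = (w, u, uinv)
            else:
                self._decomp = None  # fall back to expm
        return self._decomp

    def invalidate(self) -> None:
        self._decomp = None

    def transition_probabilities(self, t: float,
                                 rate: float = 1.0) -> np.ndarray:
        """P(t) = exp(Q * rate * t); rows sum to 1."""
        if t < 0:
            raise ValueError("negative branch length")
        dec = self._decomposition()
        if dec is None:
            p = expm(self.rate_matrix() * rate * t)
        else:
            w, u, uinv = dec
            p = (u * np.exp(w * rate * t)[None, :]) @ uinv
        p = np.clip(p, 0.0, None)
        return p / p.sum(axis=1, keepdims=True)

    def simulate(self, tree, n_sites: int, rng: np.random.Generator,
                 rates: Sequence[float] | None = None) -> dict:
        """Evolve ``n_sites`` iid sites along ``tree`` (states as indices).

        Root states are drawn from the stationary frequencies; each branch
        applies ``transition_probabilities`` at the site's rate (all 1 by
        default).  Returns ``{leaf label: int array}``.
        """
        k = self.n_states
        if rates is None:
            site_rates = np.ones(n_sites)
        else:
            site_rates = np.asarray(rates, dtype=float)
        root_states = rng.choice(k, size=n_sites, p=self.freqs)
        out: dict[str, np.ndarray] = {}
        unique_rates = np.unique(site_rates)

        def walk(node, states):
            for child in node.children:
                t = child.length or 0.0
                child_states = states.copy()
                for r in unique_rates:
                    sel = site_rates == r
                    if not sel.any():
                        continue
                    p = self.transition_probabilities(t, rate=float(r))
                    cum = p.cumsum(axis=1)
                    u = rng.random(int(sel.sum()))
                    src = states[sel]
                    child_states[sel] = (u[:, None] > cum[src]).sum(axis=1)
                if child.is_leaf:
                    out[child.label] = child_states
                else:
                    walk(child, child_states)

        walk(tree, root_states)
        return out


@dataclass
class GTRIG(_ReversibleModel):
    """General time-reversible nucleotide model with invariant sites and
    discrete-gamma rate heterogeneity.

    ``exchangeabilities`` follow the order AC, AG, AU, CG, CU, GU.
    """

    exchangeabilities: Sequence[float] = (1.0,) * 6
    frequencies: Sequence[float] = (0.25,) * 4
    p_invariant: float = 0.0
    gamma_shape: float = np.inf
    n_rate_categories: int = 4

    states = tuple(NUC)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.frequencies, dtype=float)
        _check_frequencies(self.freqs)
        if not (0 <= self.p_invariant < 1):
            raise ValueError("p_invariant must lie in [0, 1)")
        if self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")
        self._decomp = None

    def exchangeability_matrix(self) -> np.ndarray:
        s = np.zeros((4, 4))
        idx = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        for (i, j), x in zip(idx, self.exchangeabilities):
            if x < 0:
                raise ValueError("negative exchangeability")
            s[i, j] = s[j, i] = x
        return s

    def rate_matrix(self) -> np.ndarray:
        return _reversible_q(self.exchangeability_matrix(), self.freqs)

    def rate_mixture(self) -> tuple[np.ndarray, np.ndarray]:
        """(weights, rates) including the invariant class (rate 0)."""
        if np.isinf(self.gamma_shape):
            gam = np.ones(1)
        else:
            gam = discrete_gamma_rates(self.gamma_shape,
                                       self.n_rate_categories)
        p_inv = self.p_invariant
        if p_inv > 0:
            weights = np.concatenate([[p_inv],
                                      (1 - p_inv) * np.ones(len(gam)) / len(gam)])
            rates = np.concatenate([[0.0], gam / (1 - p_inv)])
        else:
            weights = np.ones(len(gam)) / len(gam)
            rates = gam
        return weights, rates

    def n_free_parameters(self) -> int:
        n = (len(self.exchangeabilities) - 1) + (len(self.freqs) - 1)
        n += 1  # p_invariant
        n += 1  # gamma shape
        return n


@dataclass
class Paired7A(_ReversibleModel):
    """General reversible 7-state base-pair model (canonical pairs + lumped
    mismatch).  Reversibility leaves base-pair reversal asymmetric: the rate
    AU->UA need not mirror UA->AU beyond detailed balance."""

    exchangeabilities: Sequence[float] = (1.0,) * 21
    frequencies: Sequence[float] = (1 / 7.0,) * 7
    p_invariant: float = 0.0
    gamma_shape: float = np.inf
    n_rate_categories: int = 4

    states = PAIR7_STATES

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.frequencies, dtype=float)
        _check_frequencies(self.freqs)
        if len(self.exchangeabilities) != 21:
            raise ValueError("7-state model needs 21 exchangeabilities")
        self._decomp = None

    def exchangeability_matrix(self) -> np.ndarray:
        s = np.zeros((7, 7))
        k = 0
        for i in range(7):
            for j in range(i + 1, 7):
                x = self.exchangeabilities[k]
                if x < 0:
                    raise ValueError("negative exchangeability")
                s[i, j] = s[j, i] = x
                k += 1
        return s

    def rate_matrix(self) -> np.ndarray:
        return _reversible_q(self.exchangeability_matrix(), self.freqs)

    def rate_mixture(self) -> tuple[np.ndarray, np.ndarray]:
        return GTRIG.rate_mixture(self)

    def n_free_parameters(self, with_rate_heterogeneity: bool = False) -> int:
        n = (len(self.exchangeabilities) - 1) + (self.n_states - 1)
        if with_rate_heterogeneity:
            n += 2
        return n


def pair16_rate_class(a: str, b: str) -> str | None:
    """Rate class of an (ordered) dinucleotide change, or None if forbidden.

    Classes among canonical states: ``single``, ``double_substitution``
    (two changes, not both transversions), ``double_transversion``.
    Single changes touching mismatch states: ``to_mismatch`` between a
    canonical and a mismatch state, ``within_mismatch`` between mismatches.
    Double changes involving a mismatch state are forbidden.
    """
    if a == b:
        return None
    diffs = [(x, y) for x, y in zip(a, b) if x != y]
    a_can, b_can = a in CANONICAL_PAIRS, b in CANONICAL_PAIRS
    if len(diffs) == 1:
        if a_can and b_can:
            return "single"
        if a_can != b_can:
            return "to_mismatch"
        return "within_mismatch"
    if a_can and b_can:
        if all(not is_transition(x, y) for x, y in diffs):
            return "double_transversion"
        return "double_substitution"
    return None


@dataclass
class Paired16A(_ReversibleModel):
    """Simplified reversible 16-state base-pair model with five rate
    classes (see module docstring)."""

    alpha_single: float = 1.0
    alpha_double_substitution: float = 0.5
    alpha_double_transversion: float = 0.25
    kappa_to_mismatch: float = 0.2
    kappa_within_mismatch: float = 0.1
    frequencies: Sequence[float] = (1 / 16.0,) * 16
    p_invariant: float = 0.0
    gamma_shape: float = np.inf
    n_rate_categories: int = 4

    states = PAIR16_STATES

    RATE_CLASSES = ("single", "double_substitution", "double_transversion",
                    "to_mismatch", "within_mismatch")

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.frequencies, dtype=float)
        _check_frequencies(self.freqs)
        for name in ("alpha_single", "alpha_double_substitution",
                     "alpha_double_transversion", "kappa_to_mismatch",
                     "kappa_within_mismatch"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative rate parameter {name}")
        self._decomp = None

    def class_rates(self) -> dict[str, float]:
        return {
            "single": self.alpha_single,
            "double_substitution": self.alpha_double_substitution,
            "double_transversion": self.alpha_double_transversion,
            "to_mismatch": self.kappa_to_mismatch,
            "within_mismatch": self.kappa_within_mismatch,
        }

    def exchangeability_matrix(self) -> np.ndarray:
        rates = self.class_rates()
        s = np.zeros((16, 16))
        for i, a in enumerate(self.states):
            for j, b in enumerate(self.states):
                if i >= j:
                    continue
                cls = pair16_rate_class(a, b)
                if cls is not None:
                    s[i, j] = s[j, i] = rates[cls]
        return s

    def rate_matrix(self) -> np.ndarray:
        return _reversible_q(self.exchangeability_matrix(), self.freqs)

    def rate_mixture(self) -> tuple[np.ndarray, np.ndarray]:
        return GTRIG.rate_mixture(self)

    def n_free_parameters(self, with_rate_heterogeneity: bool = False) -> int:
        n = (len(self.RATE_CLASSES) - 1) + (self.n_states - 1)
        if with_rate_heterogeneity:
            n += 2
        return n


def count_free_parameters(model, with_rate_heterogeneity: bool | None = None
                          ) -> int:
    """Free-parameter count excluding the overall rate-scale constraint.

    For GTR+I+G the invariant proportion and gamma shape are always part of
    the model; for the paired-site models rate heterogeneity is optional and
    off by default.
    """
    if isinstance(model, GTRIG):
        return model.n_free_parameters()
    if with_rate_heterogeneity is None:
        with_rate_heterogeneity = False
    return model.n_free_parameters(with_rate_heterogeneity)


# ---------------------------------------------------------------------------
# Data encoding and likelihood
# ---------------------------------------------------------------------------

from .alignments import GAP, IUPAC  # noqa: E402  (light circular-safe import)


def encode_nucleotide_column(column: Sequence[str]) -> np.ndarray:
    """Per-taxon indicator rows over ACGU; gap/missing marginalise."""
    out = np.zeros((len(column), 4))
    for r, ch in enumerate(column):
        ch = ch.upper().replace("T", "U")
        states = IUPAC.get(ch, "ACGU") if ch != GAP else "ACGU"
        for s in states:
            out[r, NUC.index(s)] = 1.0
    return out


def _pair_indicator(a: str, b: str, states: Sequence[str]) -> np.ndarray:
    a = a.upper().replace("T", "U")
    b = b.upper().replace("T", "U")
    sa = IUPAC.get(a, "ACGU") if a != GAP else "ACGU"
    sb = IUPAC.get(b, "ACGU") if b != GAP else "ACGU"
    dinucs = {x + y for x in sa for y in sb}
    out = np.zeros(len(states))
    if len(states) == 7:
        for d in dinucs:
            idx = states.index(d) if d in states else states.index("MM")
            out[idx] = 1.0
    else:
        for d in dinucs:
            out[states.index(d)] = 1.0
    return out


def encode_pair_column(col_a: Sequence[str], col_b: Sequence[str],
                       states: Sequence[str]) -> np.ndarray:
    return np.stack([_pair_indicator(a, b, states)
                     for a, b in zip(col_a, col_b)])


@dataclass
class PartitionData:
    """Leaf indicator tensors for one model partition.

    ``leaf_partials`` maps taxon -> array (n_sites, n_states); taxa missing
    from the map are treated as all-missing.  ``column_ids`` (optional)
    lets :func:`partitioned_loglik` verify that no alignment column is
    claimed by two partitions.
    """

    model: _ReversibleModel
    leaf_partials: dict[str, np.ndarray]
    column_ids: tuple | None = None

    @property
    def n_sites(self) -> int:
        arr = next(iter(self.leaf_partials.values()), None)
        return 0 if arr is None else arr.shape[0]


def pruning_loglik(tree, partition: PartitionData) -> float:
    """Felsenstein pruning with the model's rate mixture; missing and
    ambiguous residues are marginalised."""
    model = partition.model
    n_sites = partition.n_sites
    if n_sites == 0:
        return 0.0
    k = model.n_states
    weights, rates = model.rate_mixture()
    ones = np.ones((n_sites, k))
    site_mix = np.zeros(n_sites)
    for w, r in zip(weights, rates):
        partials: dict[int, np.ndarray] = {}
        for node in tree.postorder():
            if node.is_leaf:
                partials[id(node)] = partition.leaf_partials.get(
                    node.label, ones)
            else:
                p = np.ones((n_sites, k))
                for child in node.children:
                    pmat = model.transition_probabilities(
                        child.length or 0.0, rate=r)
                    p = p * (partials[id(child)] @ pmat.T)
                partials[id(node)] = p
        site_mix = site_mix + w * (partials[id(tree)] @ model.freqs)
    if (site_mix <= 0).any():
        return -np.inf
    return float(np.log(site_mix).sum())


def partitioned_loglik(tree, partitions: Sequence[PartitionData]) -> float:
    """Sum of per-partition pruning log-likelihoods.

    Raises ``ValueError`` when two partitions claim the same column id.
    """
    seen: set = set()
    for part in partitions:
        if part.column_ids is not None:
            dup = seen & set(part.column_ids)
            if dup:
                raise ValueError(f"columns assigned to two partitions: "
                                 f"{sorted(dup)[:5]}")
            seen |= set(part.column_ids)
    return sum(pruning_loglik(tree, p) for p in partitions)
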