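"""Two-state phylogenetic HMM for conserved-element calling.

State 0 ("conserved") emits alignment columns under the neutral tree with
every branch scaled by rho < 1; state 1 ("nonconserved") emits under the
unscaled neutral tree.  Elements are maximal conserved runs of the Viterbi
path, mapped to reference coordinates and filtered by a minimum length
(20 bp by default — short calls are unreliable and are discarded).  Scores
are summed per-column log-likelihood ratios (nats); the BED writer rounds
10*log10-odds to an integer score column.

Transition defaults follow an expected element length of 45 columns
(mu = 1/45) and 5% stationary conserved coverage; both are configuration,
not estimates, and can be refit from data with :func:`estimate_rho`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .alignment import MultipleAlignment
from .likelihood import compress_patterns, leaf_row_map, site_log_likelihoods
from .models import SubstitutionModel
from .tree import PhyloTree

__all__ = [
    "PhyloHMMParams",
    "ConservedElement",
    "emission_table",
    "forward_backward",
    "viterbi_path",
    "viterbi_elements",
    "element_log_odds",
    "estimate_rho",
]


@dataclass(frozen=True)
class PhyloHMMParams:
    """rho: conserved-state branch scale; mu: P(conserved->nonconserved);
    nu: P(nonconserved->conserved)."""

    rho: float = 0.3
    mu: float = 1.0 / 45.0
    nu: float = (1.0 / 45.0) * 0.05 / 0.95

    def __post_init__(self):
        if not (0 < self.rho <= 1):
            raise ValueError("rho must be in (0, 1]")
        if not (0 < self.mu < 1 and 0 < self.nu < 1):
            raise ValueError("mu and nu must be in (0, 1)")

    @classmethod
    def from_tuning(cls, rho: float = 0.3, expected_length: float = 45.0,
                    coverage: float = 0.05) -> "PhyloHMMParams":
        mu = 1.0 / expected_length
        return cls(rho=rho, mu=mu, nu=mu * coverage / (1.0 - coverage))

    @property
    def stationary(self) -> np.ndarray:
        z = self.mu + self.nu
        return np.array([self.nu / z, self.mu / z])

    @property
    def transition(self) -> np.ndarray:
        return np.array([[1 - self.mu, self.mu], [self.nu, 1 - self.nu]])


@dataclass
class ConservedElement:
    """A called element on the reference genome (0-based half-open)."""

    chrom: str
    start: int
    end: int
    score: float  # summed log-odds, nats
    mean_posterior: float = float("nan")
    label: str = "HCE"

    @property
    def length(self) -> int:
        return self.end - self.start

    def bed_score(self) -> int:
        return int(round(10.0 * self.score / np.log(10.0)))


# --------------------------------------------------------------------- #
def emission_table(
    aln: MultipleAlignment,
    tree: PhyloTree,
    model: SubstitutionModel,
    rho: float,
) -> np.ndarray:
    """(n_columns, 2) array of per-column (log P_conserved, log P_nonconserved)."""
    if not (0 < rho <= 1):
        raise ValueError("rho must be in (0, 1]")
    patterns, _, inverse = compress_patterns(aln.matrix)
    rows = leaf_row_map(tree, aln.species)
    con = site_log_likelihoods(tree, model, patterns, rows, scale=rho)
    non = site_log_likelihoods(tree, model, patterns, rows, scale=1.0)
    return np.column_stack([con[inverse], non[inverse]])


def forward_backward(
    emissions: np.ndarray, params: PhyloHMMParams
) -> tuple[np.ndarray, float]:
    """Posterior P(conserved) per column and the total log-likelihood.

    Scaled recursions; stable for inputs of 10^6 columns and more.
    """
    E = np.asarray(emissions, float)
    if E.ndim != 2 or E.shape[1] != 2 or E.shape[0] == 0:
        raise ValueError("emissions must be a non-empty (L, 2) array")
    L = E.shape[0]
    shift = E.max(axis=1, keepdims=True)
    shift[~np.isfinite(shift)] = 0.0
    b = np.exp(E - shift)  # per-column emission weights, max 1
    A = params.transition
    alpha = np.empty((L, 2))
    c = np.empty(L)
    a = params.stationary * b[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, L):
        a = (alpha[t - 1] @ A) * b[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    loglik = float(np.log(c).sum() + shift.sum())
    beta = np.empty((L, 2))
    beta[-1] = 1.0
    for t in range(L - 2, -1, -1):
        beta[t] = (A @ (b[t + 1] * beta[t + 1])) / c[t + 1]
    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)
    return post[:, 0], loglik


def viterbi_path(emissions: np.ndarray, params: PhyloHMMParams) -> np.ndarray:
    """Most probable state sequence (0 = conserved, 1 = nonconserved)."""
    E = np.asarray(emissions, float)
    L = E.shape[0]
    logA = np.log(params.transition)
    delta = np.log(params.stationary) + E[0]
    back = np.empty((L, 2), dtype=np.int8)
    for t in range(1, L):
        cand = delta[:, None] + logA  # cand[i, j]
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], [0, 1]] + E[t]
    states = np.empty(L, dtype=np.int8)
    states[-1] = int(np.argmax(delta))
    for t in range(L - 1, 0, -1):
        states[t - 1] = back[t, states[t]]
    return states


def _runs(mask: np.ndarray):
    """(start, end) column runs of True."""
    d = np.diff(np.concatenate([[0], mask.astype(np.int8), [0]]))
    return list(zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)))


def viterbi_elements(
    emissions: np.ndarray,
    params: PhyloHMMParams,
    ref_positions: np.ndarray,
    chrom: str = "chr1",
    min_length: int = 20,
    posterior: np.ndarray | None = None,
) -> list[ConservedElement]:
    """Conserved elements from the Viterbi path, as reference intervals.

    Columns with no reference coordinate (reference gap) cannot lie inside
    an element; conserved runs are split there.  Runs spanning fewer than
    ``min_length`` reference bases are discarded.
    """
    states = viterbi_path(emissions, params)
    if posterior is None:
        posterior, _ = forward_backward(emissions, params)
    conserved = (states == 0) & (np.asarray(ref_positions) >= 0)
    out = []
    for cs, ce in _runs(conserved):
        start = int(ref_positions[cs])
        end = int(ref_positions[ce - 1]) + 1
        if end - start < min_length:
            continue
        out.append(
            ConservedElement(
                chrom,
                start,
                end,
                score=float((emissions[cs:ce, 0] - emissions[cs:ce, 1]).sum()),
                mean_posterior=float(posterior[cs:ce].mean()),
            )
        )
    return out


def element_log_odds(element: ConservedElement, emissions: np.ndarray,
                     ref_positions: np.ndarray) -> float:
    """Summed conserved-vs-nonconserved log-likelihood ratio over an element."""
    cols = np.flatnonzero(
        (ref_positions >= element.start) & (ref_positions < element.end)
    )
    return float((emissions[cols, 0] - emissions[cols, 1]).sum())


# --------------------------------------------------------------------- #
def estimate_rho(
    aln: MultipleAlignment,
    tree: PhyloTree,
    model: SubstitutionModel,
    init: PhyloHMMParams | None = None,
    max_iter: int = 30,
    tol: float = 1e-6,
    min_columns: int = 1000,
) -> tuple[PhyloHMMParams, dict]:
    """Fit rho and the transition probabilities from an alignment.

    Alternates a Baum-Welch update of (mu, nu) with a bounded 1-D
    profile-likelihood maximisation over rho (emissions recomputed per
    candidate).  Both steps cannot decrease the observed-data
    log-likelihood, so the returned trace is monotone non-decreasing.
    """
    if aln.n_columns < min_columns:
        warnings.warn(
            f"alignment has {aln.n_columns} columns (<{min_columns}); "
            "rho estimate will be unstable"
        )
    params = init or PhyloHMMParams()
    patterns, _, inverse = compress_patterns(aln.matrix)
    rows = leaf_row_map(tree, aln.species)
    non = site_log_likelihoods(tree, model, patterns, rows, scale=1.0)[inverse]

    def emissions_for(rho):
        con = site_log_likelihoods(tree, model, patterns, rows, scale=rho)[inverse]
        return np.column_stack([con, non])

    def loglik_for(rho, mu, nu):
        _, ll = forward_backward(emissions_for(rho), PhyloHMMParams(rho, mu, nu))
        return ll

    trace = []
    converged = False
    E = emissions_for(params.rho)
    for _ in range(max_iter):
        # E-step quantities for the transition update
        post, ll = forward_backward(E, params)
        trace.append(ll)
        xi = _transition_counts(E, params)
        mu = xi[0, 1] / max(xi[0].sum(), 1e-300)
        nu = xi[1, 0] / max(xi[1].sum(), 1e-300)
        mu = float(np.clip(mu, 1e-6, 1 - 1e-6))
        nu = float(np.clip(nu, 1e-6, 1 - 1e-6))
        res = minimize_scalar(
            lambda r: -loglik_for(r, mu, nu),
            bounds=(1e-3, 1.0),
            method="bounded",
            options={"xatol": 1e-4},
        )
        new = PhyloHMMParams(float(res.x), mu, nu)
        E = emissions_for(new.rho)
        _, ll_new = forward_backward(E, new)
        if ll_new < ll - 1e-9:  # guard: keep the better iterate
            break
        params = new
        if ll_new - ll < tol:
            converged = True
            trace.append(ll_new)
            break
    if not converged:
        warnings.warn("rho estimation did not converge; returning best-so-far")
    info = {"loglik_trace": trace, "converged": converged,
            "occupancy": float(forward_backward(E, params)[0].mean())}
    return params, info


def _transition_counts(emissions: np.ndarray, params: PhyloHMMParams) -> np.ndarray:
    """Expected transition counts (2x2) from the scaled forward-backward pass."""
    E = np.asarray(emissions, float)
    L = E.shape[0]
    shift = E.max(axis=1, keepdims=True)
    shift[~np.isfinite(shift)] = 0.0
    b = np.exp(E - shift)
    A = params.transition
    alpha = np.empty((L, 2))
    c = np.empty(L)
    a = params.stationary * b[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, L):
        a = (alpha[t - 1] @ A) * b[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    beta = np.ones(2)
    xi = np.zeros((2, 2))
    for t in range(L - 2, -1, -1):
        w = b[t + 1] * beta / c[t + 1]
        xi += np.outer(alpha[t], w) * A
        beta = A @ w
    return xi


def write_bed(elements, path, name_prefix: str = "el") -> None:
    with open(path, "w") as fh:
        for i, e in enumerate(elements):
            fh.write(
                f"{e.chrom}\t{e.start}\t{e.end}\t{name_prefix}{i + 1}"
                f"|{e.label}\t{e.bed_score()}\t+\n"
            )


def write_wig(posterior: np.ndarray, ref_positions: np.ndarray, chrom: str, path) -> None:
    """fixedStep wiggle track of the conserved posterior on reference bases."""
    keep = np.asarray(ref_positions) >= 0
    pos = np.asarray(ref_positions)[keep]
    val = np.asarray(posterior)[keep]
    with open(path, "w") as fh:
        if len(pos) == 0:
            return
        breaks = np.flatnonzero(np.diff(pos) != 1)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks + 1, [len(pos)]])
        for s, e in zip(starts, ends):
            fh.write(f"fixedStep chrom={chrom} start={pos[s] + 1} step=1\n")
            fh.write("\n".join(f"{v:.5f}" for v in val[s:e]) + "\n")
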