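"""REML estimation of direct/indirect genetic variance components and BLUP.

The estimation model is the classical animal model extended with indirect
genetic and indirect (permanent) environmental effects:

    y = X b + Z_D a_D + Z_I a_I + Z_I e_I + e

with (a_D, a_I) ~ MVN(0, G x A)  (x: Kronecker product, A the pedigree
numerator relationship matrix), e_I ~ MVN(0, sigma2_eI I), e ~ MVN(0,
sigma2_e I).  X carries one fixed-effect column per herd (no intercept);
each row of Z_D points at the recipient's own genetic effect and row i of
Z_I carries one entry per analysis-side contact of cow i, holding the
analysis intensities (1 when intensities are ignored).

Restricted likelihoods, gradients and predictions are computed through
the sparse mixed-model equations (MME).  The maximizer combines
expectation-maximization (EM) and average-information (AI) candidate
steps, keeping whichever has the higher exact restricted likelihood.
The trace terms of the inverse MME coefficient matrix are exact: via a
block-arrow Cholesky with selected inversion when the problem decomposes
into herd-local blocks plus a sire border (always, for this study's
designs), via column solves on small generic systems, and by seeded
Hutchinson probes — held fixed across iterations so the iteration stays
deterministic — on large non-decomposable ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as la
from scipy import sparse
from scipy.sparse.linalg import splu

from .network import ContactNetwork
from .scenarios import VarianceComponents

__all__ = [
    "MixedModelSpec",
    "REMLFit",
    "REMLOptions",
    "a_inverse",
    "build_design",
    "restricted_loglik",
    "reml_fit",
    "blup",
]


# --------------------------------------------------------------------------
# pedigree relationship algebra
# --------------------------------------------------------------------------

def a_inverse(pedigree: pd.DataFrame) -> sparse.csc_matrix:
    """Inverse numerator relationship matrix by Henderson's rules.

    Assumes a parents-first, non-inbred pedigree (founders unrelated), as
    in the simulated two-generation population.  Returns a sparse
    symmetric matrix in pedigree row order.
    """
    animals = pedigree["animal"].to_numpy()
    pos = {int(a): i for i, a in enumerate(animals)}
    sires = pedigree["sire"].to_numpy()
    dams = pedigree["dam"].to_numpy()
    m = len(animals)
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(m):
        parents = []
        for p in (sires[i], dams[i]):
            if p != 0:
                if int(p) not in pos or pos[int(p)] >= i:
                    raise ValueError(
                        f"pedigree not parents-first (animal {animals[i]}, parent {p})"
                    )
                parents.append(pos[int(p)])
        # Mendelian-sampling variance for a non-inbred pedigree
        d = 1.0 - 0.25 * len(parents)
        if len(parents) == 2:
            d = 0.5
        alpha = 1.0 / d
        add(i, i, alpha)
        for pp in parents:
            add(i, pp, -0.5 * alpha)
            add(pp, i, -0.5 * alpha)
            for qq in parents:
                add(pp, qq, 0.25 * alpha)
    return sparse.csc_matrix(
        sparse.coo_matrix((vals, (rows, cols)), shape=(m, m))
    )


def _logdet_A(pedigree: pd.DataFrame) -> float:
    """log|A| = sum of log Mendelian-sampling variances (non-inbred pedigree)."""
    known = (pedigree[["sire", "dam"]].to_numpy() != 0).sum(axis=1)
    d = np.where(known == 2, 0.5, np.where(known == 1, 0.75, 1.0))
    return float(np.log(d).sum())


# --------------------------------------------------------------------------
# design assembly
# --------------------------------------------------------------------------

@dataclass
class MixedModelSpec:
    """Response, fixed design and random-effect incidence maps for the MME."""

    y: np.ndarray
    X: sparse.csr_matrix  # n x p, one column per herd
    Z_D: sparse.csr_matrix  # n x m, recipient's own genetic effect
    Z_I: sparse.csr_matrix  # n x m, partners' genetic effects (analysis intensities)
    Z_c: sparse.csr_matrix  # n x c, partners' permanent environmental effects
    animal_ids: np.ndarray  # length m, pedigree order
    cow_positions: np.ndarray  # indices into animal axis for phenotyped cows
    herd_ids: np.ndarray  # length p
    logdet_A: float

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def m(self) -> int:
        return self.Z_D.shape[1]

    @property
    def c(self) -> int:
        return self.Z_c.shape[1]


def build_design(
    phenos: pd.DataFrame,
    network: ContactNetwork,
    pedigree: pd.DataFrame,
    analysis_intensity: str = "ignore",
    analysis_direction: str = "as_simulated",
) -> MixedModelSpec:
    """Assemble the mixed-model design from phenotypes, network and pedigree.

    ``analysis_intensity`` selects the Z_I entries: the noisy analysis-side
    intensities (``use_noisy``), the true simulated ones (``use_true``), or
    plain 0/1 contacts (``ignore``).  On a directed network,
    ``analysis_direction="ignore_direction"`` symmetrizes: row i gains one
    entry for every arc touching i in either direction.
    """
    animal_ids = pedigree["animal"].to_numpy()
    pos = pd.Series(np.arange(animal_ids.size), index=animal_ids)
    cow_ids = phenos["cow"].to_numpy()
    if not np.isin(cow_ids, animal_ids).all():
        raise ValueError("phenotyped cow missing from the pedigree")
    n = cow_ids.size
    row_of_cow = pd.Series(np.arange(n), index=cow_ids)

    herd_ids = np.unique(phenos["herd"].to_numpy())
    herd_col = pd.Series(np.arange(herd_ids.size), index=herd_ids)
    X = sparse.csr_matrix(
        (np.ones(n), (np.arange(n), herd_col.loc[phenos["herd"]].to_numpy())),
        shape=(n, herd_ids.size),
    )
    cow_positions = pos.loc[cow_ids].to_numpy()
    Z_D = sparse.csr_matrix(
        (np.ones(n), (np.arange(n), cow_positions)), shape=(n, animal_ids.size)
    )

    e = network.edges
    col = {"use_true": "f_true", "use_noisy": "f_analysis", "ignore": None}[
        analysis_intensity
    ]
    if network.directed and analysis_direction == "as_simulated":
        rel = pd.DataFrame({"recipient": e["target"], "partner": e["source"]})
        f = e[col].to_numpy() if col else np.ones(len(e))
    else:
        rel = pd.DataFrame(
            {
                "recipient": np.concatenate([e["target"], e["source"]]),
                "partner": np.concatenate([e["source"], e["target"]]),
            }
        )
        f = (
            np.concatenate([e[col], e[col]]) if col else np.ones(2 * len(e))
        )
        if network.directed:
            # reciprocal arcs collapse to a single undirected contact
            keep = ~rel.duplicated()
            rel, f = rel[keep], f[keep.to_numpy()]
    if not rel["partner"].isin(row_of_cow.index).all():
        bad = rel.loc[~rel["partner"].isin(row_of_cow.index), "partner"].iloc[0]
        raise ValueError(f"contact references non-phenotyped animal {bad}")
    Z_I = sparse.csr_matrix(
        (
            np.asarray(f, dtype=float),
            (
                row_of_cow.loc[rel["recipient"]].to_numpy(),
                pos.loc[rel["partner"]].to_numpy(),
            ),
        ),
        shape=(n, animal_ids.size),
    )
    Z_c = Z_I[:, cow_positions].tocsr()
    return MixedModelSpec(
        y=phenos["y"].to_numpy(dtype=float),
        X=X,
        Z_D=Z_D,
        Z_I=Z_I,
        Z_c=Z_c,
        animal_ids=animal_ids,
        cow_positions=cow_positions,
        herd_ids=herd_ids,
        logdet_A=_logdet_A(pedigree),
    )


# --------------------------------------------------------------------------
# mixed-model equations
# --------------------------------------------------------------------------

class _MMEWorkspace:
    """Pieces of the MME that do not change across REML iterations."""

    def __init__(self, spec: MixedModelSpec, a_inv: sparse.spmatrix):
        self.spec = spec
        self.a_inv = sparse.csc_matrix(a_inv)
        self.T = sparse.hstack(
            [spec.X, spec.Z_D, spec.Z_I, spec.Z_c], format="csc"
        )
        self.TtT = (self.T.T @ self.T).tocsc()
        self.Tty = self.T.T @ spec.y
        self.yty = float(spec.y @ spec.y)
        p, m, c = spec.p, spec.m, spec.c
        self.slc_b = slice(0, p)
        self.slc_D = slice(p, p + m)
        self.slc_I = slice(p + m, p + 2 * m)
        self.slc_c = slice(p + 2 * m, p + 2 * m + c)
        self.dim = p + 2 * m + c
        self.q = 2 * m + c
        self._lu_a = None
        self._arrow = "unset"

    @property
    def lu_a(self):
        if self._lu_a is None:
            self._lu_a = splu(self.a_inv)
        return self._lu_a

    @property
    def arrow(self):
        if self._arrow == "unset":
            self._arrow = _build_arrow(self)
        return self._arrow


def _assemble_C(ws: _MMEWorkspace, vc: VarianceComponents):
    """MME coefficient matrix C = T'T/sigma2_e + blockdiag(0, Sigma^-1)."""
    spec = ws.spec
    G = vc.G
    sign, logdet_G = np.linalg.slogdet(G)
    if sign <= 0:
        raise ValueError("G must be positive definite inside the REML iteration")
    Ginv = np.linalg.inv(G)
    prior = sparse.block_diag(
        [
            sparse.csc_matrix((spec.p, spec.p)),
            sparse.kron(Ginv, ws.a_inv, format="csc"),
            sparse.identity(spec.c, format="csc") / vc.sigma2_eI,
        ],
        format="csc",
    )
    C = (ws.TtT / vc.sigma2_e + prior).tocsc()
    return C, Ginv, float(logdet_G)


class _FactorCommon:
    """Shared post-factorization quantities and operators."""

    def _finish(self, logdet_G: float):
        ws, vc, spec = self.ws, self.vc, self.ws.spec
        self.sol = self.solve(ws.Tty / vc.sigma2_e)
        self.e_hat = spec.y - ws.T @ self.sol
        self.yPy = (ws.yty - float(ws.Tty @ self.sol)) / vc.sigma2_e
        self.logdet_Sigma = (
            spec.m * logdet_G + 2 * spec.logdet_A + spec.c * math.log(vc.sigma2_eI)
        )
        self.loglik = -0.5 * (
            spec.n * math.log(vc.sigma2_e)
            + self.logdet_Sigma
            + self.logdet_C
            + self.yPy
        )

    def apply_P(self, x: np.ndarray) -> np.ndarray:
        """P x where P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1 (via the MME)."""
        s = self.solve(self.ws.T.T @ x / self.vc.sigma2_e)
        return (x - self.ws.T @ s) / self.vc.sigma2_e


class _Factor(_FactorCommon):
    """Generic sparse-LU factorization of the MME."""

    def __init__(self, ws: _MMEWorkspace, vc: VarianceComponents):
        self.ws = ws
        self.vc = vc
        C, self.Ginv, logdet_G = _assemble_C(ws, vc)
        self.lu = splu(C)
        diagU = self.lu.U.diagonal()
        if (diagU == 0).any():
            raise ValueError("singular mixed-model coefficient matrix")
        self.logdet_C = float(np.log(np.abs(diagU)).sum())
        self._finish(logdet_G)

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        return self.lu.solve(rhs)


class _ArrowFactor(_FactorCommon):
    """Block-arrow Cholesky factorization of the MME.

    All unknowns except a small global border (sires, and any parent with
    offspring in several herds) are local to one herd, so C permutes to a
    block-diagonal-plus-border form.  Dense per-herd Cholesky factors and a
    Schur complement on the border give fast solves, exact log-determinants
    and — crucially — an exact selected inverse for the REML trace terms.
    """

    def __init__(self, ws: _MMEWorkspace, vc: VarianceComponents):
        self.ws = ws
        self.vc = vc
        ar = ws.arrow
        C, self.Ginv, logdet_G = _assemble_C(ws, vc)
        C = C.tocsr()
        nb = ar.border_idx.size
        S = (
            C[ar.border_idx][:, ar.border_idx].toarray()
            if nb
            else np.zeros((0, 0))
        )
        self.blocks = []
        logdet_C = 0.0
        try:
            for idx in ar.herd_idx:
                rows = C[idx]
                A_h = rows[:, idx].toarray()
                cho = la.cho_factor(A_h, lower=True, check_finite=False)
                if nb:
                    B_h = rows[:, ar.border_idx].toarray()
                    W_h = la.cho_solve(cho, B_h, check_finite=False)
                    S -= B_h.T @ W_h
                else:
                    B_h = np.zeros((idx.size, 0))
                    W_h = B_h
                logdet_C += 2.0 * float(np.log(np.diag(cho[0])).sum())
                self.blocks.append((cho, B_h, W_h))
            self.S_cho = la.cho_factor(S, lower=True, check_finite=False) if nb else None
            if nb:
                logdet_C += 2.0 * float(np.log(np.diag(self.S_cho[0])).sum())
        except (np.linalg.LinAlgError, la.LinAlgError) as exc:
            raise ValueError(f"mixed-model coefficient matrix not positive definite: {exc}")
        self.logdet_C = logdet_C
        self._finish(logdet_G)

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        ar = self.ws.arrow
        nb = ar.border_idx.size
        x = np.empty_like(rhs)
        t = rhs[ar.border_idx].copy() if nb else np.zeros(0)
        ys = []
        for idx, (cho, B_h, _W) in zip(ar.herd_idx, self.blocks):
            y_h = la.cho_solve(cho, rhs[idx], check_finite=False)
            ys.append(y_h)
            if nb:
                t -= B_h.T @ y_h
        s = la.cho_solve(self.S_cho, t, check_finite=False) if nb else t
        for idx, (cho, _B, W_h), y_h in zip(ar.herd_idx, self.blocks, ys):
            x[idx] = y_h - (W_h @ s if nb else 0.0)
        if nb:
            x[ar.border_idx] = s
        return x

    def selected_traces(self) -> "_Traces":
        """Exact trace terms from the selected inverse of C.

        Uses C^-1 restricted to the herd-diagonal blocks
        (A_h^-1 + W_h S^-1 W_h'), the herd-border cross blocks (-W_h S^-1)
        and the border block S^-1 — exactly the entries needed against the
        sparsity pattern of A^-1 and the e_I diagonal.
        """
        ar = self.ws.arrow
        nb = ar.border_idx.size
        S_inv = (
            la.cho_solve(self.S_cho, np.eye(nb), check_finite=False)
            if nb
            else np.zeros((0, 0))
        )
        acc = np.zeros(3)
        for w in range(3):
            oi, oj, v = ar.tasks_border[w]
            if v.size:
                acc[w] += float(v @ S_inv[oi, oj])
        Tee = 0.0
        for h, (cho, _B, W_h) in enumerate(self.blocks):
            n_h = ar.herd_idx[h].size
            Inv = la.cho_solve(cho, np.eye(n_h), check_finite=False)
            if nb:
                WSi = W_h @ S_inv
                Inv += WSi @ W_h.T
            for w in range(3):
                oi, oj, v = ar.tasks_local[h][w]
                if v.size:
                    acc[w] += float(v @ Inv[oi, oj])
                ol, ob, v = ar.tasks_mixed[h][w]
                if v.size:
                    # C^-1[local, border] = -W_h S^-1
                    acc[w] -= float(v @ WSi[ol, ob])
            eo = ar.eI_offsets[h]
            if eo.size:
                Tee += float(Inv[eo, eo].sum())
        return _Traces(acc[0], acc[1], acc[2], Tee)


class _ArrowStructure:
    """Column partition of the MME into herd-local blocks plus a border."""

    def __init__(self, herd_idx, border_idx, tasks_local, tasks_mixed, tasks_border, eI_offsets):
        self.herd_idx = herd_idx
        self.border_idx = border_idx
        self.tasks_local = tasks_local
        self.tasks_mixed = tasks_mixed
        self.tasks_border = tasks_border
        self.eI_offsets = eI_offsets


def _build_arrow(ws: _MMEWorkspace) -> _ArrowStructure | None:
    """Detect the herd-local / border column partition, or None if the
    problem does not decompose (a pedigree link between animals local to
    different herds)."""
    spec = ws.spec
    p, m, c = spec.p, spec.m, spec.c
    # herd (1-based group) of each phenotype record = its X column + 1
    X_csr = spec.X.tocsr()
    row_herd = X_csr.indices + 1  # one entry per row
    group = np.zeros(m, dtype=int)
    group[spec.cow_positions] = row_herd
    # parents: local to a herd iff all pedigree neighbours' herds agree
    coo = sparse.coo_matrix(ws.a_inv)
    off = coo.row != coo.col
    herds_of: dict[int, set[int]] = {}
    for i, j in zip(coo.row[off], coo.col[off]):
        if group[i] == 0 and group[j] != 0:
            herds_of.setdefault(int(i), set()).add(int(group[j]))
    for i, hs in herds_of.items():
        if len(hs) == 1:
            group[i] = hs.pop()
        else:
            group[i] = -1  # border
    group[group == 0] = -1  # animals with no phenotyped relatives: border
    # a pedigree link between two different local herds breaks the structure
    gi, gj = group[coo.row[off]], group[coo.col[off]]
    if np.any((gi > 0) & (gj > 0) & (gi != gj)):
        return None

    # column order: per herd [herd effect, aD, aI, e_I], then border [aD, aI]
    col_group = np.empty(ws.dim, dtype=int)
    col_group[:p] = np.arange(1, p + 1)
    col_group[p : p + m] = group
    col_group[p + m : p + 2 * m] = group
    col_group[p + 2 * m :] = row_herd  # e_I column k belongs to record k's herd
    herd_idx = []
    col_off = np.empty(ws.dim, dtype=int)
    for h in range(1, p + 1):
        idx = np.flatnonzero(col_group == h)
        col_off[idx] = np.arange(idx.size)
        herd_idx.append(idx)
    border_idx = np.flatnonzero(col_group == -1)
    col_off[border_idx] = np.arange(border_idx.size)

    # gather tasks: tr(A^-1 C^{XY}) = sum over nnz(A^-1) of v * C^-1 entries
    colD = p + coo.row
    colI = p + m + coo.row
    colDj = p + coo.col
    colIj = p + m + coo.col
    pairs = [(colD, colDj), (colD, colIj), (colI, colIj)]  # TDD, TDI, TII
    tasks_local = [[None] * 3 for _ in range(p)]
    tasks_mixed = [[None] * 3 for _ in range(p)]
    tasks_border = [None] * 3
    gi = group[coo.row]
    gj = group[coo.col]
    for w, (ci, cj) in enumerate(pairs):
        both_b = (gi == -1) & (gj == -1)
        tasks_border[w] = (
            col_off[ci[both_b]],
            col_off[cj[both_b]],
            coo.data[both_b],
        )
        for h in range(1, p + 1):
            loc = (gi == h) & (gj == h)
            tasks_local[h - 1][w] = (
                col_off[ci[loc]],
                col_off[cj[loc]],
                coo.data[loc],
            )
            mix_i = (gi == h) & (gj == -1)
            mix_j = (gj == h) & (gi == -1)
            ol = np.concatenate([col_off[ci[mix_i]], col_off[cj[mix_j]]])
            ob = np.concatenate([col_off[cj[mix_i]], col_off[ci[mix_j]]])
            v = np.concatenate([coo.data[mix_i], coo.data[mix_j]])
            tasks_mixed[h - 1][w] = (ol, ob, v)
    eI_offsets = [
        col_off[p + 2 * m + np.flatnonzero(row_herd == h)] for h in range(1, p + 1)
    ]
    return _ArrowStructure(
        herd_idx, border_idx, tasks_local, tasks_mixed, tasks_border, eI_offsets
    )


def _make_factor(ws: _MMEWorkspace, vc: VarianceComponents) -> _FactorCommon:
    if ws.arrow is not None:
        return _ArrowFactor(ws, vc)
    return _Factor(ws, vc)


def _reduced_loglik_fixed_only(spec: MixedModelSpec, sigma2_e: float) -> float:
    """REML log-likelihood of the fixed-effects-only model (all other variances 0)."""
    X = spec.X.toarray()
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ spec.y)
    rss = float(np.sum((spec.y - X @ beta) ** 2))
    _, logdet = np.linalg.slogdet(XtX / sigma2_e)
    return -0.5 * (
        spec.n * math.log(sigma2_e) + logdet + rss / sigma2_e
    )


def restricted_loglik(
    spec: MixedModelSpec, a_inv: sparse.spmatrix, vc: VarianceComponents
) -> float:
    """Restricted log-likelihood (2*pi constant omitted) via the MME identity

        -2 l_R = n log sigma2_e + log|Sigma| + log|C| + y' P y

    which equals the dense form -(1/2)[log|V| + log|X'V^-1 X| + y'Py].
    Degenerate models with all of sigma2_aD, sigma2_aI, sigma2_eI equal to 0
    reduce to the closed-form fixed-effects-only value.
    """
    if vc.sigma2_aD == 0 and vc.sigma2_aI == 0 and vc.sigma2_eI == 0:
        return _reduced_loglik_fixed_only(spec, vc.sigma2_e)
    return _make_factor(_MMEWorkspace(spec, a_inv), vc).loglik


# --------------------------------------------------------------------------
# trace machinery
# --------------------------------------------------------------------------

@dataclass
class _Traces:
    """Traces of C^{-1} blocks against the prior structure.

    TDD = tr(A^-1 C^{aD,aD}), TDI = tr(A^-1 C^{aD,aI}),
    TII = tr(A^-1 C^{aI,aI}), Tee = tr(C^{eI,eI}).
    """

    TDD: float
    TDI: float
    TII: float
    Tee: float

    def against_prior(self, Ginv: np.ndarray, sigma2_eI: float) -> float:
        """tr(C^{uu} Sigma^-1)."""
        return (
            Ginv[0, 0] * self.TDD
            + 2 * Ginv[0, 1] * self.TDI
            + Ginv[1, 1] * self.TII
            + self.Tee / sigma2_eI
        )

    def against(self, H: np.ndarray) -> float:
        """tr(C^{uu} (H x A^-1)) for a symmetric 2x2 H on the genetic blocks."""
        return H[0, 0] * self.TDD + 2 * H[0, 1] * self.TDI + H[1, 1] * self.TII


def _traces_exact(fac: _Factor) -> _Traces:
    ws = fac.ws
    m, c = ws.spec.m, ws.spec.c
    A_inv = ws.a_inv
    TDD = TDI = TII = Tee = 0.0
    rhs = np.zeros(ws.dim)
    # column-by-column selected inverse; only viable for small systems
    for j in range(m):
        rhs[:] = 0.0
        rhs[ws.slc_D.start + j] = 1.0
        s = fac.solve(rhs)
        colD = s[ws.slc_D]
        colI = s[ws.slc_I]
        aj = A_inv[:, j].toarray().ravel()
        TDD += float(aj @ colD)
        TDI += float(aj @ colI)
    for j in range(m):
        rhs[:] = 0.0
        rhs[ws.slc_I.start + j] = 1.0
        s = fac.solve(rhs)
        aj = A_inv[:, j].toarray().ravel()
        TII += float(aj @ s[ws.slc_I])
    for j in range(c):
        rhs[:] = 0.0
        rhs[ws.slc_c.start + j] = 1.0
        Tee += float(fac.solve(rhs)[ws.slc_c.start + j])
    return _Traces(TDD, TDI, TII, Tee)


class _HutchinsonProbes:
    """Fixed Rademacher probes over the random-effect block.

    Holding the probes fixed across iterations makes the estimated traces a
    smooth deterministic function of the parameters, so the optimizer can
    meet tight convergence criteria; the Monte-Carlo error then acts as a
    tiny fixed perturbation of the objective rather than as noise.
    """

    def __init__(self, ws: _MMEWorkspace, n_probes: int, seed: int):
        rng = np.random.default_rng(seed)
        self.Z = rng.choice([-1.0, 1.0], size=(ws.dim, n_probes))
        self.Z[ws.slc_b, :] = 0.0
        self.ws = ws
        # A^-1 z precomputed per probe for the two genetic blocks
        self.AinvZD = ws.a_inv @ self.Z[ws.slc_D, :]
        self.AinvZI = ws.a_inv @ self.Z[ws.slc_I, :]

    def estimate(self, fac: _Factor) -> _Traces:
        ws = self.ws
        S = np.column_stack([fac.solve(self.Z[:, k]) for k in range(self.Z.shape[1])])
        SD, SI, Sc = S[ws.slc_D], S[ws.slc_I], S[ws.slc_c]
        n_probes = self.Z.shape[1]
        TDD = float(np.sum(self.AinvZD * SD)) / n_probes
        TII = float(np.sum(self.AinvZI * SI)) / n_probes
        TDI = 0.5 * float(np.sum(self.AinvZI * SD) + np.sum(self.AinvZD * SI)) / n_probes
        Tee = float(np.sum(self.Z[ws.slc_c] * Sc)) / n_probes
        return _Traces(TDD, TDI, TII, Tee)


# --------------------------------------------------------------------------
# score, average information, EM update
# --------------------------------------------------------------------------

_DG = {
    "sigma2_aD": np.array([[1.0, 0.0], [0.0, 0.0]]),
    "sigma_aDI": np.array([[0.0, 1.0], [1.0, 0.0]]),
    "sigma2_aI": np.array([[0.0, 0.0], [0.0, 1.0]]),
}
PARAM_NAMES = ("sigma2_aD", "sigma_aDI", "sigma2_aI", "sigma2_eI", "sigma2_e")


def _vc_from_theta(theta: np.ndarray) -> VarianceComponents:
    return VarianceComponents(
        sigma2_aD=theta[0],
        sigma2_aI=theta[2],
        sigma_aDI=theta[1],
        sigma2_eI=theta[3],
        sigma2_e=theta[4],
    )


def _working_variates(fac: _Factor) -> list[np.ndarray]:
    """w_k = (dV/dtheta_k) P y for each parameter."""
    ws = fac.ws
    spec = ws.spec
    Py = fac.apply_P(spec.y)  # equals e_hat / sigma2_e
    tD = spec.Z_D.T @ Py
    tI = spec.Z_I.T @ Py
    # apply A without forming it: A t = A_inv \ t
    AtD = ws.lu_a.solve(tD)
    AtI = ws.lu_a.solve(tI)
    w = [
        spec.Z_D @ AtD,
        spec.Z_D @ AtI + spec.Z_I @ AtD,
        spec.Z_I @ AtI,
        spec.Z_c @ (spec.Z_c.T @ Py),
        Py,
    ]
    return w, Py


def _score_and_ai(
    fac: _Factor, traces: _Traces
) -> tuple[np.ndarray, np.ndarray]:
    ws = fac.ws
    spec = ws.spec
    vc = fac.vc
    Ginv = fac.Ginv
    w, Py = _working_variates(fac)
    Pw = [fac.apply_P(wk) for wk in w]
    k = len(w)
    AI = 0.5 * np.array([[w[i] @ Pw[j] for j in range(k)] for i in range(k)])
    AI = 0.5 * (AI + AI.T)

    tr_prior = traces.against_prior(Ginv, vc.sigma2_eI)
    score = np.empty(k)
    for idx, name in enumerate(PARAM_NAMES[:3]):
        dG = _DG[name]
        H = Ginv @ dG @ Ginv
        trPV = spec.m * float(np.trace(Ginv @ dG)) - traces.against(H)
        score[idx] = -0.5 * (trPV - float(Py @ w[idx]))
    trPV_eI = spec.c / vc.sigma2_eI - traces.Tee / vc.sigma2_eI**2
    score[3] = -0.5 * (trPV_eI - float(Py @ w[3]))
    trP = (spec.n - spec.p - ws.q + tr_prior) / vc.sigma2_e
    score[4] = -0.5 * (trP - float(Py @ w[4]))
    return score, AI


def _em_update(fac: _Factor, traces: _Traces) -> np.ndarray:
    ws = fac.ws
    spec = ws.spec
    vc = fac.vc
    aD = fac.sol[ws.slc_D]
    aI = fac.sol[ws.slc_I]
    eI = fac.sol[ws.slc_c]
    A_inv = ws.a_inv
    g11 = (float(aD @ (A_inv @ aD)) + traces.TDD) / spec.m
    g12 = (float(aD @ (A_inv @ aI)) + traces.TDI) / spec.m
    g22 = (float(aI @ (A_inv @ aI)) + traces.TII) / spec.m
    s_eI = (float(eI @ eI) + traces.Tee) / spec.c
    tr_prior = traces.against_prior(fac.Ginv, vc.sigma2_eI)
    s_e = (
        float(fac.e_hat @ fac.e_hat)
        + vc.sigma2_e * (spec.p + ws.q - tr_prior)
    ) / spec.n
    return np.array([g11, g12, g22, s_eI, s_e])


# --------------------------------------------------------------------------
# the fit driver
# --------------------------------------------------------------------------

@dataclass
class REMLOptions:
    max_iter: int = 200
    em_warmup: int = 5
    tol_param: float = 1e-6
    tol_loglik: float = 1e-8
    n_probes: int = 32
    probe_seed: int = 20_240_101
    exact_trace_max: int = 1500  # use column-solve traces when 2m+c is below this
    max_rg: float = 0.999
    boundary_frac: float = 1e-8
    step_halvings: int = 10
    verbose: bool = False


@dataclass
class REMLFit:
    estimates: VarianceComponents
    r_g_hat: float
    loglik: float
    converged: bool
    n_iter: int
    boundary: bool
    ebv: pd.DataFrame
    fixed_effects: pd.DataFrame
    history: list = field(default_factory=list, repr=False)
    #: asymptotic standard errors (inverse AI matrix at the last iterate),
    #: in parameter order sigma2_aD, sigma_aDI, sigma2_aI, sigma2_eI, sigma2_e
    se: np.ndarray | None = None


def _project(theta: np.ndarray, floor_g: float, floor_e: float, max_rg: float) -> np.ndarray:
    t = theta.copy()
    t[0] = max(t[0], floor_g)
    t[2] = max(t[2], floor_g)
    t[3] = max(t[3], floor_g)
    t[4] = max(t[4], floor_e)
    bound = max_rg * math.sqrt(t[0] * t[2])
    t[1] = float(np.clip(t[1], -bound, bound))
    return t


def default_init(spec: MixedModelSpec) -> np.ndarray:
    """50/50 split of within-herd phenotypic variance between direct genetic
    and residual; small positive indirect variances; zero covariance."""
    y = spec.y
    herd_mean = spec.X @ (
        np.asarray(spec.X.sum(axis=0)).ravel() ** -1 * (spec.X.T @ y)
    )
    var_y = float(np.var(y - herd_mean, ddof=1))
    mean_contacts = spec.Z_I.getnnz() / spec.n if spec.n else 1.0
    small = 0.01 * var_y / max(mean_contacts, 1.0)
    return np.array([0.5 * var_y, 0.0, small, small, 0.5 * var_y])


def reml_fit(
    spec: MixedModelSpec,
    a_inv: sparse.spmatrix,
    init: VarianceComponents | np.ndarray | None = None,
    options: REMLOptions | None = None,
) -> REMLFit:
    """Maximize the restricted likelihood over the five (co)variance
    components, subject to G positive semi-definite (|r_g| <= 0.999).

    EM warm start, then average-information steps with step-halving and an
    EM fallback when a step is inadmissible or decreases the likelihood.
    Hitting the iteration cap returns ``converged=False`` rather than
    raising.  The returned EBVs are the BLUP solutions at the final
    estimates, for all pedigree animals including non-phenotyped parents.
    """
    opt = options or REMLOptions()
    ws = _MMEWorkspace(spec, a_inv)
    if init is None:
        theta = default_init(spec)
    elif isinstance(init, VarianceComponents):
        theta = np.array(
            [init.sigma2_aD, init.sigma_aDI, init.sigma2_aI, init.sigma2_eI, init.sigma2_e]
        )
    else:
        theta = np.asarray(init, dtype=float).copy()
    y_scale = max(float(np.var(spec.y, ddof=1)), 1e-12)
    floor_g = opt.boundary_frac * y_scale
    floor_e = 1e-6 * y_scale
    theta = _project(theta, floor_g, floor_e, opt.max_rg)

    use_arrow = ws.arrow is not None
    use_exact = not use_arrow and ws.q <= opt.exact_trace_max
    probes = (
        None
        if use_arrow or use_exact
        else _HutchinsonProbes(ws, opt.n_probes, opt.probe_seed)
    )

    def factor(th):
        return _make_factor(ws, _vc_from_theta(th))

    def traces_of(fac):
        if use_arrow:
            return fac.selected_traces()
        return _traces_exact(fac) if use_exact else probes.estimate(fac)

    fac = factor(theta)
    history = [(theta.copy(), fac.loglik)]
    converged = False
    n_iter = 0
    last_AI = None
    for n_iter in range(1, opt.max_iter + 1):
        traces = traces_of(fac)
        theta_old, ll_old = theta.copy(), fac.loglik
        score = AI = None
        pinned = np.zeros(5, dtype=bool)
        if n_iter > opt.em_warmup:
            score, AI = _score_and_ai(fac, traces)
            last_AI = AI
            # a variance the likelihood pushes below ~1e-5 of var(y) is
            # scientifically zero: pin it at the floor so the remaining
            # parameters converge at full speed instead of crawling along
            # an EM-style geometric decay toward the boundary
            for idx in (0, 2, 3, 4):
                if theta[idx] <= 1e-5 * y_scale and score[idx] < 0:
                    pinned[idx] = True
            # a zero genetic variance makes the covariance zero as well
            if pinned[0] or pinned[2]:
                pinned[1] = True
        floors = np.array([floor_g, 0.0, floor_g, floor_g, floor_e])
        # EM candidate: monotone and robust (its trace terms are not amplified
        # by G^-1, so it stays reliable where the score is noisy)
        theta_em = _em_update(fac, traces)
        theta_em[pinned] = floors[pinned]
        theta_em = _project(theta_em, floor_g, floor_e, opt.max_rg)
        try:
            fac_em = factor(theta_em)
        except (ValueError, RuntimeError):
            theta_em, fac_em = None, None
        theta_new, fac_new = theta_em, fac_em
        if n_iter > opt.em_warmup:
            # AI candidate on the active set, with trust region and halving
            active = ~pinned
            try:
                step = np.zeros(5)
                step[active] = np.linalg.solve(
                    AI[np.ix_(active, active)]
                    + 1e-10 * np.eye(int(active.sum())) * np.trace(AI),
                    score[active],
                )
            except np.linalg.LinAlgError:
                step = None
            if step is not None:
                theta = theta.copy()
                theta[pinned] = floors[pinned]
                # variances move at most a factor of 5 per step (plus an
                # absolute allowance so near-zero components can still grow)
                alpha = 1.0
                for idx in (0, 2, 3, 4):
                    if step[idx] < 0:
                        alpha = min(alpha, 0.8 * theta[idx] / -step[idx])
                    elif step[idx] > 0:
                        alpha = min(alpha, (4 * theta[idx] + 0.05 * y_scale) / step[idx])
                step = step * alpha
                for _ in range(opt.step_halvings):
                    cand = _project(theta + step, floor_g, floor_e, opt.max_rg)
                    try:
                        fac_cand = factor(cand)
                    except (ValueError, RuntimeError):
                        step *= 0.5
                        continue
                    if fac_cand.loglik >= ll_old - 1e-10 * abs(ll_old):
                        # accept the better of the EM and AI candidates
                        if fac_new is None or fac_cand.loglik >= fac_new.loglik:
                            theta_new, fac_new = cand, fac_cand
                        break
                    step *= 0.5
        if fac_new is None:  # both candidates inadmissible: shrink toward current
            theta_new = _project(
                0.5 * (theta + theta_old), floor_g, floor_e, opt.max_rg
            )
            fac_new = factor(theta_new)
        theta, fac = theta_new, fac_new
        history.append((theta.copy(), fac.loglik))
        if opt.verbose:
            print(f"iter {n_iter:3d} loglik {fac.loglik:.6f} theta {theta}")
        # variances below ~1e-5 of the phenotypic variance are scientifically
        # zero; don't let their micro-movements at the floor block convergence
        denom = np.maximum(np.abs(theta_old), 1e-5 * y_scale)
        rel_param = float(np.max(np.abs(theta - theta_old) / denom))
        rel_ll = abs(fac.loglik - ll_old) / max(abs(ll_old), 1.0)
        if n_iter > opt.em_warmup and rel_param < opt.tol_param and rel_ll < opt.tol_loglik:
            converged = True
            break

    vc_hat = _vc_from_theta(theta)
    se = None
    if last_AI is not None:
        try:
            se = np.sqrt(np.diag(np.linalg.inv(last_AI)))
        except np.linalg.LinAlgError:
            se = None
    boundary = bool(
        theta[0] <= floor_g * 1.01
        or theta[2] <= floor_g * 1.01
        or theta[3] <= floor_g * 1.01
        or abs(vc_hat.r_g) >= opt.max_rg * 0.999
    )
    ebv, fixed = _solutions_frame(spec, fac)
    return REMLFit(
        estimates=vc_hat,
        r_g_hat=vc_hat.r_g,
        loglik=fac.loglik,
        converged=converged,
        n_iter=n_iter,
        boundary=boundary,
        ebv=ebv,
        fixed_effects=fixed,
        history=history,
        se=se,
    )


def _solutions_frame(spec: MixedModelSpec, fac: _Factor):
    ws = fac.ws
    ebv = pd.DataFrame(
        {
            "animal": spec.animal_ids,
            "aD_hat": fac.sol[ws.slc_D],
            "aI_hat": fac.sol[ws.slc_I],
        }
    )
    fixed = pd.DataFrame({"herd": spec.herd_ids, "estimate": fac.sol[ws.slc_b]})
    return ebv, fixed


def blup(
    spec: MixedModelSpec, a_inv: sparse.spmatrix, vc: VarianceComponents
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """BLUP solutions of the MME at fixed variance components.

    Returns (ebv, fixed_effects): per-animal predicted direct and indirect
    genetic effects (all pedigree animals) and the herd-effect solutions.
    """
    fac = _make_factor(_MMEWorkspace(spec, a_inv), vc)
    return _solutions_frame(spec, fac)
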