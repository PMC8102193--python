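"""Temporal cascade network reverse engineering.

The model couples every actor (gene or protein, by symbol) to candidate
regulators from the same or an earlier temporal cluster through transfer
matrices acting on whole time profiles:

    x_l[p, .] = sum_k omega_{k l} F_{m(k) m(l)} x_k[p, .] + eps_l[p, .]

where ``m`` maps an actor to its temporal cluster (rank of its first
significant response time), ``F_ij`` is a T x T strictly lower-triangular
transfer matrix (sources act only on strictly later target times) and
``omega`` is a sparse signed connection-strength matrix.  Estimation
alternates a prior-weighted LASSO in ``omega`` with ridge least squares in
the ``F`` entries; edge sets are made robust by stability selection over
row subsamples, with prior edges favored through a multiplicative penalty
factor kappa < 1 in every refit.

The module is organised statsmodels-style: :class:`CascadeNetworkModel` is
built from per-individual fold-change profiles, ``fit`` returns a
:class:`CascadeResults`, and stability selection / cross-validation hang
off the model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso

logger = logging.getLogger(__name__)

_RIDGE = 1e-6
# numerical support tolerance on unit-rms-scaled data: true scaled weights
# are O(0.1..1); spurious path remnants at small lambda are orders smaller
_SUPPORT_TOL = 1e-4
_LAM_FLOOR = 1e-3  # minimal penalty keeping subsampled (p > n) fits unique


# ---------------------------------------------------------------------------
# domain types


@dataclass
class PriorNetwork:
    """Known-interaction edge list (a stand-in for a curated database).

    Edges are (source, target, confidence in (0, 1]); duplicates are merged
    keeping the maximum confidence.
    """

    edges: list

    def __post_init__(self):
        merged = {}
        for s, t, c in self.edges:
            c = float(c)
            if not 0 < c <= 1:
                raise ValueError(f"confidence for {s}->{t} must be in (0, 1]")
            key = (str(s).upper(), str(t).upper())
            merged[key] = max(merged.get(key, 0.0), c)
        self.edges = [(s, t, c) for (s, t), c in sorted(merged.items())]

    @property
    def edge_set(self):
        return {(s, t) for s, t, _ in self.edges}

    @property
    def confidence(self):
        return {(s, t): c for s, t, c in self.edges}

    def __len__(self):
        return len(self.edges)


@dataclass
class ClusterAssignment:
    """Actor -> temporal cluster map (contiguous ranks, 1 = earliest onset)."""

    m: dict
    onset_time: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.m:
            ranks = sorted(set(self.m.values()))
            if ranks != list(range(1, len(ranks) + 1)):
                raise ValueError("cluster indices must be contiguous from 1")

    @property
    def n_clusters(self):
        return max(self.m.values()) if self.m else 0


def assign_clusters(significant_times) -> ClusterAssignment:
    """Cluster actors by the rank of their first significant time index.

    Parameters
    ----------
    significant_times : mapping
        actor -> iterable of significant time indices (or a mapping
        time -> direction, as produced by the signatures module).  Actors
        with no significant time are excluded with a logged reason.
    """
    onsets = {}
    for actor, times in significant_times.items():
        times = list(times)
        if not times:
            logger.info("actor %s has no significant time; excluded from clustering", actor)
            continue
        onsets[str(actor).upper()] = min(times)
    distinct = sorted(set(onsets.values()))
    rank = {t: i + 1 for i, t in enumerate(distinct)}
    return ClusterAssignment(
        m={a: rank[t] for a, t in onsets.items()}, onset_time=dict(onsets)
    )


@dataclass
class InferredNetwork:
    """Directed edge list with stability frequencies and cluster annotations.

    ``edges`` columns: source, target, omega_hat, stability_frequency,
    sign, source_cluster, target_cluster, in_prior.
    """

    edges: pd.DataFrame
    actors: list
    clusters: ClusterAssignment
    pi_thr: float = 0.0
    frequencies: np.ndarray = None  # (N, N) selection frequencies, all candidates
    actor_modality: dict = None     # actor -> {"transcript", "protein"}

    def __post_init__(self):
        m = self.clusters.m
        for row in self.edges.itertuples():
            if m[row.source] > m[row.target]:
                raise ValueError(f"acausal inferred edge {row.source}->{row.target}")
        if len(self.edges) and (self.edges["stability_frequency"] < self.pi_thr).any():
            raise ValueError("edge below the stability threshold")

    @property
    def edge_set(self):
        return set(zip(self.edges["source"], self.edges["target"]))

    def degree_table(self):
        """Total (in + out) degree per actor over retained edges."""
        deg = {a: 0 for a in self.actors}
        for row in self.edges.itertuples():
            deg[row.source] += 1
            deg[row.target] += 1
        return (
            pd.DataFrame({"actor": list(deg), "degree": list(deg.values())})
            .sort_values(["degree", "actor"], ascending=[False, True])
            .reset_index(drop=True)
        )


def degree_summary(net: InferredNetwork, threshold: int = 10):
    """Hub actors (total degree >= threshold) and the full degree table.

    The default threshold of 10 statistical links is the conventional hub
    criterion for this kind of cascade network.
    """
    table = net.degree_table()
    hubs = set(table.loc[table["degree"] >= threshold, "actor"])
    return hubs, table


# ---------------------------------------------------------------------------
# predictors and solvers


def shift_matrix(T: int, lag: int = 1) -> np.ndarray:
    """Unit subdiagonal shift: output t = input t - lag (zero-padded)."""
    F = np.zeros((T, T))
    for t in range(lag, T):
        F[t, t - lag] = 1.0
    return F


def build_predictor(F: np.ndarray, source_series: np.ndarray) -> np.ndarray:
    """Apply a transfer matrix to a source time profile.

    ``F`` must be strictly lower triangular in time, so entry t of the
    result depends only on source entries s < t.
    """
    F = np.asarray(F, dtype=float)
    x = np.asarray(source_series, dtype=float)
    T = x.shape[0]
    if F.shape != (T, T):
        raise ValueError(f"F must be {T}x{T}, got {F.shape}")
    if not np.array_equal(F, np.tril(F, -1)):
        raise ValueError("F must be strictly lower triangular in time")
    return F @ x


def _weighted_lasso(X, y, lam, w):
    """argmin_b 0.5 ||y - X b||^2 + lam * sum_j w_j |b_j|."""
    if X.shape[1] == 0:
        return np.zeros(0)
    if lam == 0:
        return np.linalg.lstsq(X, y, rcond=None)[0]
    Xs = X / w  # b_j = z_j / w_j turns weighted L1 into plain L1
    n = X.shape[0]
    est = Lasso(alpha=lam / n, fit_intercept=False, max_iter=100000, tol=1e-10)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(Xs, y)
    return est.coef_ / w


# ---------------------------------------------------------------------------
# results


@dataclass
class CascadeResults:
    """Converged cascade model: sparse weights, transfer matrices, diagnostics."""

    model: "CascadeNetworkModel"
    omega: np.ndarray            # (N, N), omega[k, l] = weight of k -> l
    F: dict                      # (i, j) -> T x T strictly lower triangular
    objective_path: list
    converged: bool
    n_iter: int
    lam: float
    kappa: float
    residual_scale: np.ndarray   # per-actor rms residual

    @property
    def support(self):
        return np.abs(self.omega) > _SUPPORT_TOL

    def edge_list(self):
        """(source, target) pairs in the fitted support, lexicographic order."""
        actors = self.model.actors
        ks, ls = np.nonzero(self.support)
        return sorted((actors[k], actors[l]) for k, l in zip(ks, ls))

    def edges(self):
        m = self.model.clusters.m
        prior = self.model.prior_edge_set
        rows = []
        for s, t in self.edge_list():
            k, l = self.model.index[s], self.model.index[t]
            w = self.omega[k, l]
            rows.append(
                dict(
                    source=s, target=t, omega_hat=w, sign=int(np.sign(w)),
                    source_cluster=m[s], target_cluster=m[t],
                    in_prior=(s, t) in prior,
                )
            )
        return pd.DataFrame(
            rows,
            columns=["source", "target", "omega_hat", "sign",
                     "source_cluster", "target_cluster", "in_prior"],
        )

    def to_network(self) -> InferredNetwork:
        """View this single fit as a network (stability frequency 1 on support)."""
        edges = self.edges()
        edges.insert(3, "stability_frequency", 1.0)
        freq = self.support.astype(float)
        return InferredNetwork(
            edges=edges, actors=list(self.model.actors),
            clusters=self.model.clusters, pi_thr=0.0, frequencies=freq,
        )

    def summary(self):
        mod = self.model
        lines = [
            "Cascade network model",
            "=" * 54,
            f"Actors:                 {mod.n_actors}",
            f"Individuals:            {mod.n_individuals}",
            f"Time points:            {mod.n_times}",
            f"Temporal clusters:      {mod.clusters.n_clusters}",
            f"Prior edges:            {len(mod.prior_edge_set)}",
            f"lambda:                 {self.lam:g}",
            f"kappa (prior factor):   {self.kappa:g}",
            f"Selected edges:         {int(self.support.sum())}",
            f"Iterations:             {self.n_iter} "
            f"({'converged' if self.converged else 'not converged'})",
            f"Objective:              {self.objective_path[-1]:.6g}",
            f"Median residual scale:  {np.median(self.residual_scale):.4g}",
            "=" * 54,
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# the model


class CascadeNetworkModel:
    """Penalized cascade regression over temporal fold-change profiles.

    Parameters
    ----------
    series : ndarray, shape (n_actors, n_individuals, T)
        Per-individual post-stimulation profiles (log2 fold changes vs T0).
        Each actor x individual profile is scaled to unit root-mean-square;
        the zero at T0 is meaningful, so profiles are not mean-centered
        (centering would destroy the exact linear-lag representation).
        NaN entries (missing protein points) are treated as zero response
        after scaling.
    actors : list of str
    clusters : ClusterAssignment
        Candidate regulators of target l are {k : m(k) <= m(l), k != l}.
    prior : PriorNetwork, optional
    kappa : float in (0, 1]
        Multiplicative LASSO penalty factor for prior-listed edges; 1 means
        no prior favoring.
    confidence_weighted : bool
        If True the factor for a prior edge with confidence c is
        ``1 - (1 - kappa) * c`` (interpolates between kappa and 1).
    """

    def __init__(self, series, actors, clusters, prior=None, kappa=0.5,
                 confidence_weighted=False):
        series = np.asarray(series, dtype=float)
        if series.ndim != 3:
            raise ValueError("series must be (n_actors, n_individuals, T)")
        self.actors = [str(a).upper() for a in actors]
        if not self.actors:
            raise ValueError("model needs at least one actor")
        if series.shape[0] != len(self.actors):
            raise ValueError("actor list does not match series")
        missing = [a for a in self.actors if a not in clusters.m]
        if missing:
            raise ValueError(f"actors without cluster assignment: {missing[:5]}")
        self.clusters = clusters
        self.index = {a: i for i, a in enumerate(self.actors)}
        self.kappa = float(kappa)
        if not 0 < self.kappa <= 1:
            raise ValueError("kappa must be in (0, 1]")
        self.confidence_weighted = confidence_weighted
        self.prior = prior
        self.prior_edge_set = prior.edge_set if prior is not None else set()
        self._prior_conf = prior.confidence if prior is not None else {}

        self.scaled = self._scale(series)
        self.n_actors, self.n_individuals, self.n_times = self.scaled.shape
        self._m = np.array([clusters.m[a] for a in self.actors])
        # candidate regulators per target, lexicographic by symbol; targets
        # in the earliest cluster are exogenous stimulus inputs (their T1
        # response precedes every observed profile) and get empty models
        order = np.argsort(np.array(self.actors))
        self.candidates = []
        for l in range(self.n_actors):
            if self._m[l] == 1:
                cand = []
            else:
                cand = [k for k in order if k != l and self._m[k] <= self._m[l]]
            self.candidates.append(np.array(cand, dtype=int))
        self._shift_cache = {}  # design columns under the initial delay F

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_fold_changes(cls, fc, clusters, prior=None, kappa=0.5,
                          confidence_weighted=False, group=None):
        """Build the model from a FoldChangeTensor, keeping clustered actors.

        ``group`` optionally restricts to individuals of one group.
        """
        keep_ind = (
            [i for i, g in enumerate(fc.groups) if g == group]
            if group is not None else list(range(fc.n_individuals))
        )
        actors = [a for a in fc.features if a in clusters.m]
        idx = [fc.features.index(a) for a in actors]
        series = fc.log2fc[np.ix_(idx, range(fc.n_times), keep_ind)]
        series = np.transpose(series, (0, 2, 1))  # (N, P, T)
        return cls(series, actors, clusters, prior=prior, kappa=kappa,
                   confidence_weighted=confidence_weighted)

    @staticmethod
    def _scale(series):
        # one scale per actor across all individuals: a per-individual scale
        # would give each individual a different effective omega and destroy
        # the shared-coefficient structure of the stacked regression
        x = np.nan_to_num(series, nan=0.0)
        rms = np.sqrt((x ** 2).mean(axis=(1, 2), keepdims=True))
        rms[rms == 0] = 1.0
        return x / rms

    def _penalty_weights(self, l):
        w = np.ones(len(self.candidates[l]))
        tgt = self.actors[l]
        for j, k in enumerate(self.candidates[l]):
            key = (self.actors[k], tgt)
            if key in self.prior_edge_set:
                if self.confidence_weighted:
                    w[j] = 1.0 - (1.0 - self.kappa) * self._prior_conf[key]
                else:
                    w[j] = self.kappa
        return w

    def _stacked_target(self, l, rows=None):
        y = self.scaled[l].ravel()  # (P*T,), p-major
        return y if rows is None else y[rows]

    def _design(self, l, F, rows=None, cache=None):
        """Design matrix for target l: one column per candidate regulator."""
        cand = self.candidates[l]
        j = self._m[l]
        cols = np.empty((self.n_individuals * self.n_times, len(cand)))
        for c, k in enumerate(cand):
            key = (self._m[k], j, k)
            if cache is not None and key in cache:
                col = cache[key]
            else:
                col = (F[(self._m[k], j)] @ self.scaled[k].T).T.ravel()
                if cache is not None:
                    cache[key] = col
            cols[:, c] = col
        return cols if rows is None else cols[rows]

    # -- estimation -----------------------------------------------------------

    def fit(self, lam, max_iter=5, tol=1e-6, refit_ols=False, rows=None) -> CascadeResults:
        """Alternate prior-weighted LASSO in omega with ridge refits of F.

        ``rows`` optionally restricts the stacked (individual, time)
        observation rows used by the LASSO step (subsampled fits skip the
        F refit and keep the initial unit-delay transfer matrices).
        """
        N, P, T = self.scaled.shape
        cluster_pairs = sorted(
            {(int(self._m[k]), int(self._m[l]))
             for l in range(N) for k in self.candidates[l]}
        )
        F = {cp: shift_matrix(T) for cp in cluster_pairs}
        omega = np.zeros((N, N))
        obj_path = []
        converged = False
        n_iter = 0
        for it in range(max_iter):
            n_iter = it + 1
            # the iteration-0 design under the unit-delay F never changes
            # across calls, so it is cached on the model (stability
            # selection and cross-validation reuse it heavily)
            cache = self._shift_cache if it == 0 else {}
            for l in range(N):
                cand = self.candidates[l]
                if len(cand) == 0:
                    continue
                X = self._design(l, F, rows=rows, cache=cache)
                y = self._stacked_target(l, rows=rows)
                w = self._penalty_weights(l)
                beta = _weighted_lasso(X, y, lam, w)
                omega[:, l] = 0.0
                omega[cand, l] = beta
            obj = self._objective(omega, F, lam, rows=rows, cache=cache)
            obj_path.append(obj)
            if it > 0 and abs(obj_path[-2] - obj) <= tol * max(1.0, abs(obj_path[-2])):
                converged = True
                break
            if it == max_iter - 1:
                break
            if rows is not None:
                break  # subsampled fits keep the initial transfer matrices
            self._refit_F(omega, F)
        if not converged and max_iter > 1 and rows is None:
            logger.warning("cascade fit did not converge in %d iterations", max_iter)
        if refit_ols:
            self._ols_refit(omega, F, rows=rows, cache=cache)
            obj_path.append(self._objective(omega, F, lam, rows=rows, cache=cache))
        resid = self._residual_scale(omega, F, cache=cache)
        return CascadeResults(
            model=self, omega=omega, F=F, objective_path=obj_path,
            converged=converged or max_iter == 1, n_iter=n_iter,
            lam=lam, kappa=self.kappa, residual_scale=resid,
        )

    def _predict_stacked(self, l, omega, F, cache=None):
        cand = self.candidates[l]
        if len(cand) == 0:
            return np.zeros(self.n_individuals * self.n_times)
        X = self._design(l, F, cache=cache)
        return X @ omega[cand, l]

    def _objective(self, omega, F, lam, rows=None, cache=None):
        obj = 0.0
        for l in range(self.n_actors):
            pred = self._predict_stacked(l, omega, F, cache=cache)
            y = self.scaled[l].ravel()
            r = y - pred
            if rows is not None:
                r = r[rows]
            w = self._penalty_weights(l)
            obj += 0.5 * float(r @ r) + lam * float(w @ np.abs(omega[self.candidates[l], l]))
        return obj

    def _residual_scale(self, omega, F, cache=None):
        out = np.empty(self.n_actors)
        for l in range(self.n_actors):
            r = self.scaled[l].ravel() - self._predict_stacked(l, omega, F, cache=cache)
            out[l] = np.sqrt(float(r @ r) / r.size)
        return out

    def _refit_F(self, omega, F):
        """Gauss-Seidel ridge refit of each transfer matrix row by row.

        For cluster pair (i, j): over all targets l in cluster j and
        individuals p, the combined upstream signal is
        u_lp = sum_{k in cluster i} omega[k, l] x_kp, and row t of F_ij is
        the ridge LS fit of the partial residual at time t on u_lp[:t].
        """
        N, P, T = self.scaled.shape
        support = np.abs(omega) > _SUPPORT_TOL
        for (i, j) in sorted(F):
            targets = []
            for l in range(N):
                if self._m[l] != j:
                    continue
                ks = [k for k in self.candidates[l] if self._m[k] == i and support[k, l]]
                if ks:
                    targets.append((l, ks))
            if not targets:
                continue
            U, R = [], []
            for l, ks in targets:
                u = np.tensordot(omega[ks, l], self.scaled[ks], axes=(0, 0))  # (P, T)
                # partial residual: remove other cluster pairs' contributions
                other = np.zeros((P, T))
                for i2 in sorted({self._m[k] for k in self.candidates[l]}):
                    if i2 == i:
                        continue
                    ks2 = [k for k in self.candidates[l]
                           if self._m[k] == i2 and support[k, l]]
                    if ks2:
                        u2 = np.tensordot(omega[ks2, l], self.scaled[ks2], axes=(0, 0))
                        other += (F[(i2, j)] @ u2.T).T
                U.append(u)
                R.append(self.scaled[l] - other)
            U = np.concatenate(U, axis=0)  # (n_eq, T)
            R = np.concatenate(R, axis=0)
            Fij = np.zeros((T, T))
            for t in range(1, T):
                A = U[:, :t]
                b = R[:, t]
                G = A.T @ A + _RIDGE * np.eye(t)
                Fij[t, :t] = np.linalg.solve(G, A.T @ b)
            F[(i, j)] = Fij

    def _ols_refit(self, omega, F, rows=None, cache=None):
        """Post-selection OLS of omega on the selected support."""
        for l in range(self.n_actors):
            cand = self.candidates[l]
            sel = [j for j, k in enumerate(cand) if abs(omega[k, l]) > _SUPPORT_TOL]
            omega[cand, l] = 0.0
            if not sel:
                continue
            X = self._design(l, F, rows=rows, cache=cache)[:, sel]
            y = self._stacked_target(l, rows=rows)
            omega[cand[sel], l] = np.linalg.lstsq(X, y, rcond=None)[0]

    # -- model selection ------------------------------------------------------

    def cross_validate(self, lam_grid, max_iter=1, tol=1e-6):
        """Grouped cross-validation of lambda, one individual left out per fold.

        Fits use the unit-delay transfer parameterization (the shared
        design lets the whole lambda path be fitted warm-started per
        target).  Returns ``(lam_best, table)`` where the table holds
        per-fold held-out mean squared prediction errors.  Ties (within
        1e-12) break toward the larger, sparser lambda.  With a single
        individual the fold structure falls back to two time blocks with a
        logged warning.
        """
        lam_grid = sorted(float(l) for l in lam_grid)
        N, P, T = self.scaled.shape
        records = []
        if P >= 2:
            F = {cp: shift_matrix(T)
                 for l in range(N) for cp in
                 {(int(self._m[k]), int(self._m[l])) for k in self.candidates[l]}}
            for p_out in range(P):
                train_rows = np.concatenate(
                    [np.arange(p * T, (p + 1) * T) for p in range(P) if p != p_out]
                )
                test_rows = np.arange(p_out * T, (p_out + 1) * T)
                fold_err = {lam: [] for lam in lam_grid}
                for l in range(N):
                    if len(self.candidates[l]) == 0:
                        continue
                    X = self._design(l, F, cache=self._shift_cache)
                    y = self.scaled[l].ravel()
                    w = self._penalty_weights(l)
                    Xw = X[train_rows] / w
                    # capped iterations: held-out error needs no
                    # support-grade precision
                    est = Lasso(alpha=1.0, fit_intercept=False, warm_start=True,
                                max_iter=3000, tol=1e-7)
                    n_train = len(train_rows)
                    for lam in sorted(lam_grid, reverse=True):
                        est.alpha = max(lam, 1e-12) / n_train
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore", ConvergenceWarning)
                            est.fit(Xw, y[train_rows])
                        beta = est.coef_ / w
                        resid = y[test_rows] - X[test_rows] @ beta
                        fold_err[lam].append(float(np.mean(resid ** 2)))
                for lam in lam_grid:
                    records.append(
                        dict(fold=p_out, lam=lam, mse=float(np.mean(fold_err[lam])))
                    )
        else:
            logger.warning("single individual: falling back to time-blocked folds")
            half = T // 2
            blocks = [np.arange(half), np.arange(half, T)]
            for f, rows in enumerate(blocks):
                other = blocks[1 - f]
                for lam in lam_grid:
                    res = self.fit(lam, max_iter=1, rows=rows)
                    errs = []
                    for l in range(N):
                        pred = self._predict_stacked(l, res.omega, res.F)
                        y = self.scaled[l].ravel()
                        errs.append(np.mean((y[other] - pred[other]) ** 2))
                    records.append(dict(fold=f, lam=lam, mse=float(np.mean(errs))))
        table = pd.DataFrame(records)
        mean_err = table.groupby("lam")["mse"].mean()
        best = mean_err.min()
        lam_best = max(l for l in lam_grid if mean_err[l] <= best + 1e-12)
        return lam_best, table

    def _heldout_error(self, res, heldout_individuals):
        errs = []
        for l in range(self.n_actors):
            cand = self.candidates[l]
            for p in heldout_individuals:
                y = self.scaled[l, p]
                pred = np.zeros(self.n_times)
                for k in cand:
                    w = res.omega[k, l]
                    if abs(w) > _SUPPORT_TOL:
                        pred += w * (res.F[(self._m[k], self._m[l])] @ self.scaled[k, p])
                errs.append(np.mean((y - pred) ** 2))
        return float(np.mean(errs))

    def stability_selection(self, lam, B=100, subsample_fraction=0.5,
                            pi_thr=0.6, seed=0, max_iter=1) -> InferredNetwork:
        """Weighted stability selection of the edge set.

        ``B`` refits on random subsamples (without replacement) of the
        stacked observation rows; an edge is retained iff its selection
        frequency is >= ``pi_thr``.  The prior acts through kappa in every
        refit.  Deterministic given ``seed``.
        """
        if B < 2:
            raise ValueError("B must be >= 2")
        if not 0 < subsample_fraction < 1:
            raise ValueError("subsample_fraction must be in (0, 1)")
        if not 0.5 <= pi_thr <= 1:
            raise ValueError("pi_thr must be in [0.5, 1]")
        N, P, T = self.scaled.shape
        n_rows = P * T
        n_sub = max(2, int(round(subsample_fraction * n_rows)))
        max_cand = max((len(c) for c in self.candidates), default=0)
        lam_eff = lam
        if n_sub < 2 * max_cand and lam < _LAM_FLOOR:
            logger.warning(
                "subsample of %d rows is below twice the candidate count (%d); "
                "applying a lambda floor of %g", n_sub, max_cand, _LAM_FLOOR,
            )
            lam_eff = _LAM_FLOOR
        rng = np.random.default_rng([int(seed), 404])
        counts = np.zeros((N, N))
        for _ in range(B):
            rows = np.sort(rng.choice(n_rows, size=n_sub, replace=False))
            res = self.fit(lam_eff, max_iter=max_iter, rows=rows)
            counts += res.support
        freq = counts / B
        full = self.fit(lam_eff, max_iter=max_iter)
        m = self.clusters.m
        rows_out = []
        for l in range(N):
            tgt = self.actors[l]
            for k in self.candidates[l]:
                f = freq[k, l]
                if f >= pi_thr:
                    src = self.actors[k]
                    w = full.omega[k, l]
                    rows_out.append(
                        dict(
                            source=src, target=tgt, omega_hat=float(w),
                            stability_frequency=float(f),
                            sign=int(np.sign(w)) if abs(w) > _SUPPORT_TOL else 0,
                            source_cluster=m[src], target_cluster=m[tgt],
                            in_prior=(src, tgt) in self.prior_edge_set,
                        )
                    )
        edges = pd.DataFrame(
            rows_out,
            columns=["source", "target", "omega_hat", "stability_frequency",
                     "sign", "source_cluster", "target_cluster", "in_prior"],
        ).sort_values(["source", "target"]).reset_index(drop=True)
        return InferredNetwork(
            edges=edges, actors=list(self.actors), clusters=self.clusters,
            pi_thr=pi_thr, frequencies=freq,
        )


# ---------------------------------------------------------------------------
# spec-surface convenience wrappers


def fit_cascade(series, actors, clusters, prior=None, lam=0.1, kappa=0.5,
                max_iter=5, tol=1e-6, refit_ols=False) -> CascadeResults:
    model = CascadeNetworkModel(series, actors, clusters, prior=prior, kappa=kappa)
    return model.fit(lam, max_iter=max_iter, tol=tol, refit_ols=refit_ols)


def cross_validate_lambda(series, actors, clusters, prior=None, lam_grid=(0.05, 0.1, 0.2, 0.5, 1.0),
                          kappa=0.5, max_iter=3):
    model = CascadeNetworkModel(series, actors, clusters, prior=prior, kappa=kappa)
    lam_best, _table = model.cross_validate(lam_grid, max_iter=max_iter)
    return lam_best


def stability_select(series, actors, clusters, prior=None, lam=0.1, kappa=0.5,
                     B=100, subsample_fraction=0.5, pi_thr=0.6, seed=0) -> InferredNetwork:
    model = CascadeNetworkModel(series, actors, clusters, prior=prior, kappa=kappa)
    return model.stability_selection(
        lam, B=B, subsample_fraction=subsample_fraction, pi_thr=pi_thr, seed=seed
    )
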