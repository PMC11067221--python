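"""Self-contained verification experiments for the whole pipeline.

Each function recomputes one property of the method from scratch at desk
scale: factorized-versus-explicit tensor agreement, noiseless planted-model
recovery, metric agreement with brute-force enumeration oracles, hierarchical
consistency audits, the GO-LTR-versus-Naive ordering on a synthetic benchmark,
and cluster-split hygiene.  The oracles here are deliberately written as
naive loops, independent of the vectorised implementation paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np

from . import ltr
from .baselines import naive_scores
from .metrics import EvalConfig, evaluate
from .ontology import (AnnotationSet, information_content,
                       propagate_scores_max, propagate_true_path)
from .synthetic import (SimConfig, annotations_from_labels, make_toy_ontology,
                        plant_model, sample_multiview, toy_label_space)
from .views import cluster_cv_folds
from .synthetic import simulate_clusters


# ---------------------------------------------------------------- tensor

def _contract(T: np.ndarray, xs) -> float:
    total = 0.0
    for idx in itertools.product(*(range(n) for n in T.shape)):
        term = T[idx]
        for d, j in enumerate(idx):
            term *= xs[d][j]
        total += term
    return total


def tensor_oracle_agreement(n_models: int = 100, seed: int = 0) -> dict:
    """Factorized forward vs explicit-tensor contraction on random models.

    Random identity-activation models with up to 3 views of dims <= 5 and
    rank <= 4; returns the worst absolute disagreement seen for both the
    forward evaluation and individual polynomial coefficients.
    """
    rng = np.random.default_rng(seed)
    worst_fwd = 0.0
    worst_coef = 0.0
    for k in range(n_models):
        n_d = int(rng.integers(1, 4))
        dims = [int(rng.integers(2, 6)) for _ in range(n_d)]
        n_t = int(rng.integers(1, 5))
        params = ltr.init_params(dims, 1, n_t, seed=seed + 7 * k + 1)
        params.lam = rng.normal(size=n_t)
        params.Q = np.ones_like(params.Q)
        T = ltr.explicit_weight_tensor(params)
        xs = [rng.normal(size=d) for d in dims]
        diff = abs(ltr.forward(params, xs)[0] - _contract(T, xs))
        worst_fwd = max(worst_fwd, diff)
        for _ in range(5):
            idx = tuple(int(rng.integers(d)) for d in dims)
            cdiff = abs(ltr.polynomial_coefficient(params, idx) - T[idx])
            worst_coef = max(worst_coef, cdiff)
    return {"n_models": n_models, "max_forward_diff": worst_fwd,
            "max_coefficient_diff": worst_coef}


# ------------------------------------------------------------- recovery

def planted_recovery(seed: int = 0, m: int = 2000, m_test: int = 500,
                     dims=(20, 20), n_t: int = 3,
                     epochs: int = 500, n_restarts: int = 3) -> dict:
    """Noiseless planted-model recovery with matched rank.

    Fits a fresh model on targets generated by a planted 2-view model and
    reports the final training objective, held-out score correlation with
    the truth, held-out MSE, and the worst per-epoch constraint residual.
    CP factorizations are non-convex, so the fit uses the standard
    multi-start protocol: ``n_restarts`` seeded initialisations, keeping
    the run with the lowest final training objective.
    """
    cfg = SimConfig(seed=seed, m=m + m_test, view_dims=tuple(dims), n_t=n_t)
    truth = plant_model(cfg, n_y=5)
    rng = np.random.default_rng(seed + 1)
    X = [rng.normal(size=(m + m_test, d)) for d in dims]
    Y = ltr.predict_scores(truth, X)
    Xtr, Xte = [x[:m] for x in X], [x[m:] for x in X]
    est = report = None
    for r in range(n_restarts):
        init = ltr.init_params(list(dims), 5, n_t, seed=seed + 2 + 1000 * r)
        cand, cand_rep = ltr.fit_params(
            init, Xtr, Y[:m], C_lambda=0.0, epochs=epochs, batch_size=128,
            learning_rate=0.01, seed=seed + 2 + 1000 * r)
        if report is None or cand_rep.objective[-1] < report.objective[-1]:
            est, report = cand, cand_rep
    S = ltr.predict_scores(est, Xte)
    corr = float(np.corrcoef(S.ravel(), Y[m:].ravel())[0, 1])
    return {
        "final_objective": report.objective[-1],
        "heldout_correlation": corr,
        "heldout_mse": float(np.mean((S - Y[m:]) ** 2)),
        "max_constraint_residual": max(report.constraint_residuals),
        "epochs": report.epochs_run,
    }


# ------------------------------------------------------------- metrics

def _oracle_metrics(Y, S, ic, taus):
    """Brute-force Fmax/WFmax/Smin/AUPRC/AUROC by explicit enumeration."""
    m, n = Y.shape

    def sweep(w):
        points = []
        for tau in taus:
            prs, rcs, n_called = [], [], 0
            for i in range(m):
                tp = sum(w[j] for j in range(n) if S[i, j] >= tau and Y[i, j])
                pred = sum(w[j] for j in range(n) if S[i, j] >= tau)
                tw = sum(w[j] for j in range(n) if Y[i, j])
                if pred > 0:
                    n_called += 1
                    prs.append(tp / pred)
                rcs.append(tp / tw if tw > 0 else 1.0)
            if n_called:
                points.append((sum(prs) / n_called, sum(rcs) / m))
        return points

    def best_f(points):
        return max((2 * p * r / (p + r) for p, r in points if p + r > 0),
                   default=0.0)

    f = best_f(sweep(np.ones(n)))
    wf = best_f(sweep(ic))
    s_best = np.inf
    for tau in taus:
        ru = mi = 0.0
        for i in range(m):
            for j in range(n):
                called = S[i, j] >= tau
                if Y[i, j] and not called:
                    ru += ic[j]
                elif called and not Y[i, j]:
                    mi += ic[j]
        s_best = min(s_best, float(np.hypot(ru / m, mi / m)))
    pts = sweep(np.ones(n))
    area = 0.0
    rc_prev = 0.0
    for p, r in reversed(pts):
        area += p * (r - rc_prev)
        rc_prev = r
    pos = [S[i, j] for i in range(m) for j in range(n) if Y[i, j]]
    neg = [S[i, j] for i in range(m) for j in range(n) if not Y[i, j]]
    if pos and neg:
        wins = sum(1.0 if p > q else (0.5 if p == q else 0.0)
                   for p in pos for q in neg)
        roc = wins / (len(pos) * len(neg))
    else:
        roc = None
    return {"fmax": f, "wfmax": wf, "smin": s_best, "auprc": area,
            "auroc": roc}


def metric_oracle_agreement(n_fixtures: int = 50, seed: int = 0) -> dict:
    """Vectorised metrics vs brute-force enumeration on random fixtures."""
    rng = np.random.default_rng(seed)
    cfg = EvalConfig()
    worst = {k: 0.0 for k in ("fmax", "wfmax", "smin", "auprc", "auroc")}
    for _ in range(n_fixtures):
        m = int(rng.integers(2, 11))
        n = int(rng.integers(2, 9))
        Y = rng.integers(0, 2, size=(m, n)).astype(float)
        S = np.round(rng.random((m, n)), 2)
        ic = rng.random(n) * 3
        rep = evaluate(Y, S, ic, cfg)
        oracle = _oracle_metrics(Y, S, ic, cfg.taus)
        for k in worst:
            a, b = getattr(rep, k), oracle[k]
            if a is None or b is None:
                continue
            worst[k] = max(worst[k], abs(a - b))
    # perfect-prediction sanity on a fresh fixture
    Y = rng.integers(0, 2, size=(6, 5)).astype(float)
    Y[0] = 1
    rep = evaluate(Y, Y, np.ones(5), cfg)
    return {"n_fixtures": n_fixtures,
            "max_metric_oracle_diff": max(worst.values()),
            "perfect_fmax": rep.fmax, "perfect_wfmax": rep.wfmax,
            "perfect_smin": rep.smin}


# ---------------------------------------------------------- consistency

def consistency_audit(n_fixtures: int = 100, seed: int = 0) -> dict:
    """Closure, parent>=child and idempotence audits on random toy DAGs."""
    rng = np.random.default_rng(seed)
    violations = 0
    for k in range(n_fixtures):
        cfg = SimConfig(seed=seed + k, m=0,
                        dag_depth=int(rng.integers(2, 4)),
                        dag_branching=int(rng.integers(2, 4)),
                        multi_parent_fraction=float(rng.random() * 0.5))
        dag = make_toy_ontology(cfg)
        space = toy_label_space(dag)
        terms = space.terms
        annots = AnnotationSet(entries={
            f"p{i}": {terms[j] for j in
                      rng.choice(len(terms), size=min(3, len(terms)),
                                 replace=False)}
            for i in range(5)
        })
        closed = propagate_true_path(annots, dag)
        twice = propagate_true_path(closed, dag)
        for p, s in closed.entries.items():
            for t in s:
                if not dag.ancestors(t) <= s:
                    violations += 1
            if twice.entries[p] != s:
                violations += 1
        S = rng.random((4, len(space)))
        out = propagate_scores_max(S, space)
        if not np.allclose(propagate_scores_max(out, space), out):
            violations += 1
        if np.any(out < S):
            violations += 1
        for j in range(len(space)):
            for a in space.ancestors_in_space[j]:
                if np.any(out[:, a] < out[:, j] - 1e-12):
                    violations += 1
    return {"n_fixtures": n_fixtures, "violations": violations}


# ------------------------------------------------------------ benchmark

def synthetic_benchmark(seed: int = 0, m: int = 1000, n_y: int = 30,
                        dims=(20, 20), n_t_true: int = 3, n_t_fit: int = 8,
                        epochs: int = 100) -> dict:
    """Train the latent-tensor model and Naive on one cluster-held-out fold.

    Reproduces, on synthetic data, the qualitative ordering that the
    tensor model beats the frequency baseline on Fmax (higher) and Smin
    (lower); also reports constraint feasibility across training epochs.
    """
    cfg = SimConfig(seed=seed, m=m, n_y=n_y, view_dims=tuple(dims),
                    n_t=n_t_true, dag_depth=3, dag_branching=4,
                    n_clusters=37)
    dag = make_toy_ontology(cfg)
    space = toy_label_space(dag, cfg.n_y)
    truth = plant_model(cfg, n_y=len(space))
    ds = sample_multiview(cfg, truth, space)
    annots = propagate_true_path(annotations_from_labels(ds, space), dag)
    space.ic = information_content(annots, dag, space)
    folds = cluster_cv_folds(ds.clusters, ds.roster, n_folds=10, seed=seed)
    tr_ids, va_ids, te_ids = folds.folds[0]
    pos = {p: i for i, p in enumerate(ds.roster)}
    tr = ds.subset([pos[p] for p in tr_ids + va_ids])
    te = ds.subset([pos[p] for p in te_ids])

    est = ltr.LatentTensorReconstruction(
        n_t=n_t_fit, epochs=epochs, batch_size=128, learning_rate=0.01,
        random_state=seed).fit(tr.X, tr.Y)
    S = propagate_scores_max(est.predict(te.X), space)
    rep = evaluate(te.Y, S, ic=space.ic)
    rep_naive = evaluate(te.Y, naive_scores(tr.Y, te.n_samples),
                         ic=space.ic)
    return {
        "ltr_fmax": rep.fmax, "naive_fmax": rep_naive.fmax,
        "ltr_smin": rep.smin, "naive_smin": rep_naive.smin,
        "ltr_auprc": rep.auprc, "naive_auprc": rep_naive.auprc,
        "ltr_coverage": rep.coverage,
        "n_test": te.n_samples, "n_labels": len(space),
        "max_constraint_residual": max(est.report_.constraint_residuals),
    }


# ----------------------------------------------------------------- splits

def split_hygiene_audit(seed: int = 0, m: int = 200, n_clusters: int = 37,
                        n_folds: int = 10) -> dict:
    """Exhaustive check that no cluster spans the train/test boundary."""
    clusters = simulate_clusters(m, n_clusters, seed=seed)
    roster = list(clusters)
    plan = cluster_cv_folds(clusters, roster, n_folds=n_folds, seed=seed + 1)
    overlaps = 0
    for tr, va, te in plan.folds:
        train_side = {clusters[p] for p in tr} | {clusters[p] for p in va}
        test_side = {clusters[p] for p in te}
        overlaps += len(train_side & test_side)
    return {"m": m, "n_clusters": n_clusters, "n_folds": n_folds,
            "cluster_overlaps": overlaps}
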