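"""Synthetic trees, traits and family-aggregated datasets.

The analysis pipeline consumes a dated family-level tree plus, per family,
only the minimum, maximum and species count of body length. This module
generates data with exactly that structure from known ground truth so every
stage can be exercised and calibrated without the original compilation:

1. grow an ultrametric pure-birth (Yule) species tree;
2. evolve a log-size trait on it under any of the six evolutionary models;
3. slice the tree at a chosen age — each lineage crossing the slice founds
   a "family" — and record, per family, min/max of exp(trait) and member
   count, plus an induced family tree with one representative tip per
   family (kept at full depth, so the family tree stays ultrametric).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evomodels import MODELS, fit_model_set, fit_trait_model, model_covariance
from .macrocaic import parametric_bootstrap_test
from .signal import blomberg_k_with_se
from .tipdist import FamilyRecord, TipDistribution, build_tip_distributions
from .tree import Phylogeny

__all__ = [
    "SyntheticDataset",
    "simulate_yule_tree",
    "simulate_trait",
    "aggregate_to_families",
    "parameter_recovery_experiment",
]


def simulate_yule_tree(n_tips: int, birth_rate: float = 0.1,
                       seed: int | None = None) -> Phylogeny:
    """Ultrametric pure-birth tree with exactly ``n_tips`` tips.

    Starting from a crown split into two lineages, with k extant lineages
    the waiting time to the next speciation is Exp(birth_rate * k); a
    uniformly chosen lineage splits. After the (n-1)th split one further
    Exp(birth_rate * n) epoch is added before stopping, so the expected
    crown age is ``sum_{k=2..n} 1 / (birth_rate * k)``. Branch lengths are
    in the same time units as 1/birth_rate (My for a per-My rate).
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if not (birth_rate > 0):
        raise ValueError("birth rate must be positive")
    rng = np.random.default_rng(seed)
    parent = [-1, 0, 0]
    birth = [0.0, 0.0, 0.0]      # time each lineage (node) came into being
    labels: list[str | None] = [None, None, None]
    active = [1, 2]
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        i = int(rng.integers(k))
        nd = active.pop(i)
        for _ in range(2):
            parent.append(nd)
            birth.append(t)
            labels.append(None)
            active.append(len(parent) - 1)
    t += rng.exponential(1.0 / (birth_rate * n_tips))
    blen = [0.0] * len(parent)
    active_set = set(active)
    # a branch ends when its lineage splits (= birth time of its children)
    # or, for extant lineages, at the present
    split_time: dict[int, float] = {}
    for nd in range(len(parent)):
        p = parent[nd]
        if p >= 0:
            split_time[p] = birth[nd]
    for nd in range(len(parent)):
        if parent[nd] < 0:
            blen[nd] = 0.0
        elif nd in active_set:
            blen[nd] = t - birth[nd]
        else:
            blen[nd] = split_time[nd] - birth[nd]
    tip_counter = 0
    for nd in active:
        tip_counter += 1
        labels[nd] = f"t{tip_counter}"
    return Phylogeny(parent, blen, labels)


def simulate_trait(tree: Phylogeny, model: str = "BM", sigma2: float = 0.01,
                   z0: float = 0.0, shape: float | None = None,
                   se=None, seed: int | None = None) -> np.ndarray:
    """One MVN draw of tip values under an evolutionary model.

    Covariance is ``sigma2 * model_covariance(model, shape, C) +
    diag(se^2)``; ``se`` adds independent observation noise per tip.
    Returns values in tree tip-label order.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    C = tree.covariance()
    if model == "SSP" and not tree.is_ultrametric():
        raise ValueError("SSP simulation requires an ultrametric tree")
    V = sigma2 * model_covariance(model, shape, C, tree.depth)
    n = tree.n_tips
    if se is not None:
        sev = np.asarray(se, dtype=float)
        if sev.ndim == 0:
            sev = np.full(n, float(sev))
        V = V + np.diag(sev**2)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n)
    # robust to the singular sigma2 = 0 case
    w, U = np.linalg.eigh(V)
    w = np.clip(w, 0.0, None)
    return z0 + U @ (np.sqrt(w) * z)


@dataclass
class SyntheticDataset:
    """Species-level truth plus the family-aggregated view of it."""

    species_tree: Phylogeny
    species_traits: np.ndarray          # ln(mm), tree tip order
    family_of: dict[str, str]           # species tip label -> family name
    family_tree: Phylogeny
    family_records: list[FamilyRecord]
    generating_model: str
    parameters: dict
    seed: int | None

    def tip_distributions(self, se_floor: float = 1e-6) -> list[TipDistribution]:
        return build_tip_distributions(self.family_records, se_floor=se_floor)


def aggregate_to_families(species_tree: Phylogeny, species_traits,
                          slice_age: float, seed: int | None = None,
                          generating_model: str = "BM",
                          parameters: dict | None = None) -> SyntheticDataset:
    """Aggregate a species-level simulation into family min/max/count records.

    ``slice_age`` (My before the present) cuts the ultrametric tree; every
    branch crossing the cut founds a family comprising its descendant tips.
    Each family record keeps only exp(trait) min/max and the member count;
    the family tree keeps one seeded-random representative species per
    family (pruned, so representative tips retain their full root-to-tip
    depth and the family tree is ultrametric). Major-clade labels are the
    root's daughter subtrees (``clade_1``, ``clade_2``, ...).
    """
    x = np.asarray(species_traits, dtype=float)
    if x.shape != (species_tree.n_tips,):
        raise ValueError("species_traits must align with species tree tips")
    T = species_tree.depth
    if not (0 < slice_age < T):
        raise ValueError(f"slice_age must lie in (0, tree depth {T:.4g})")
    cutoff = T - slice_age
    depth = species_tree.node_depths()
    labels = species_tree.tip_labels
    tip_pos = {nd: k for k, nd in enumerate(species_tree.tip_ids)}
    # tips below each node
    below: dict[int, list[int]] = {}
    for nd in species_tree.postorder():
        if species_tree.is_tip(nd):
            below[nd] = [tip_pos[nd]]
        else:
            below[nd] = [i for c in species_tree.children(nd) for i in below[c]]
    # founders: nodes whose branch spans the cutoff
    founders = [
        nd for nd in species_tree.preorder()
        if nd != species_tree.root
        and depth[species_tree.parent(nd)] < cutoff <= depth[nd]
    ]
    if len(founders) < 3:
        raise ValueError(
            f"slice at age {slice_age} yields only {len(founders)} families (< 3)"
        )
    # clade labels from the root's daughters
    clade_of_node: dict[int, str] = {}
    for i, c in enumerate(species_tree.children(species_tree.root), start=1):
        stack = [c]
        while stack:
            nd = stack.pop()
            clade_of_node[nd] = f"clade_{i}"
            stack.extend(species_tree.children(nd))
    rng = np.random.default_rng(seed)
    records, family_of, reps = [], {}, {}
    for j, nd in enumerate(founders, start=1):
        name = f"F{j:04d}"
        members = below[nd]
        vals = x[members]
        records.append(FamilyRecord(
            taxon=name,
            min_mm=float(np.exp(vals.min())),
            max_mm=float(np.exp(vals.max())),
            richness=len(members),
            clade=clade_of_node[nd],
        ))
        rep = labels[members[int(rng.integers(len(members)))]]
        reps[name] = rep
        for i in members:
            family_of[labels[i]] = name
    family_tree = species_tree.prune_to_tips(reps.values())
    # relabel representative tips with family names
    rep_to_family = {v: k for k, v in reps.items()}
    relabeled = Phylogeny(
        [family_tree.parent(i) for i in range(family_tree.n_nodes)],
        family_tree.branch_lengths,
        [rep_to_family.get(family_tree.label_of(i), family_tree.label_of(i))
         for i in range(family_tree.n_nodes)],
    )
    return SyntheticDataset(
        species_tree=species_tree,
        species_traits=x,
        family_of=family_of,
        family_tree=relabeled,
        family_records=records,
        generating_model=generating_model,
        parameters=dict(parameters or {}),
        seed=seed,
    )


DEFAULT_RECOVERY_CONFIG = {
    "model": "BM",
    "sigma2": 0.01,
    "z0": 2.0,
    "shape": None,
    "n_species": 300,
    "birth_rate": 0.1,
    "n_replicates": 20,
    "mode": "species",          # "species": fit tips directly; "family": aggregate
    "slice_age": None,           # default: 40% of expected crown age (family mode)
    "se_floor": 1e-6,
    "fit_models": ["BM", "lambda", "WN"],
    "n_boot": 2000,
    "run_signal": True,
    "run_macrocaic": False,
}


def parameter_recovery_experiment(config: dict | None = None,
                                  seed: int = 0) -> dict:
    """Simulate-and-refit validation harness for the whole pipeline.

    Per replicate: simulate a Yule tree and a trait under the generating
    model; in ``species`` mode fit directly to the simulated tips (se = 0);
    in ``family`` mode aggregate to families, build tip distributions and
    run the family-level analyses (signal, model set, optionally
    macroCAIC). The report is a pure function of (config, seed).
    """
    cfg = dict(DEFAULT_RECOVERY_CONFIG)
    if config:
        unknown = set(config) - set(cfg)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(config)
    master = np.random.default_rng(seed)
    rep_seeds = master.integers(0, 2**31 - 1, size=(cfg["n_replicates"], 3))
    reps = []
    for r in range(cfg["n_replicates"]):
        s_tree, s_trait, s_analysis = (int(v) for v in rep_seeds[r])
        tree = simulate_yule_tree(cfg["n_species"], cfg["birth_rate"], seed=s_tree)
        trait = simulate_trait(
            tree, model=cfg["model"], sigma2=cfg["sigma2"], z0=cfg["z0"],
            shape=cfg["shape"], seed=s_trait,
        )
        rep: dict = {"replicate": r}
        if cfg["mode"] == "species":
            fit_tree, fit_x, fit_se = tree, trait, None
        elif cfg["mode"] == "family":
            slice_age = cfg["slice_age"]
            if slice_age is None:
                expected_age = sum(
                    1.0 / (cfg["birth_rate"] * k)
                    for k in range(2, cfg["n_species"] + 1)
                )
                slice_age = 0.4 * expected_age
            ds = aggregate_to_families(tree, trait, slice_age, seed=s_analysis,
                                       generating_model=cfg["model"])
            tips = ds.tip_distributions(se_floor=cfg["se_floor"])
            fit_tree = ds.family_tree.resolve_polytomies(seed=s_analysis)
            by = {t.taxon: t for t in tips}
            fit_x = {l: by[l].log_mean for l in fit_tree.tip_labels}
            fit_se = {l: by[l].se for l in fit_tree.tip_labels}
            rep["n_families"] = len(tips)
            if cfg["run_macrocaic"]:
                bres = parametric_bootstrap_test(
                    fit_tree, tips, metric="rrd", n_reps=cfg["n_boot"],
                    seed=s_analysis,
                )
                rep["macrocaic_slope"] = bres.observed_slope
                rep["macrocaic_significant"] = bres.significant
        else:
            raise ValueError("mode must be 'species' or 'family'")
        bm = fit_trait_model(fit_tree, fit_x, se=fit_se, model="BM")
        rep["sigma2_hat"] = bm.sigma2
        rep["z0_hat"] = bm.z0
        if cfg["run_signal"]:
            rep["K"] = blomberg_k_with_se(fit_tree, fit_x, fit_se).K
        if cfg["fit_models"]:
            comp = fit_model_set(fit_tree, fit_x, se=fit_se,
                                 models=cfg["fit_models"], seed=s_analysis)
            rep["favoured_model"] = comp.favoured.model
            lam = [f for f in comp.fits if f.model == "lambda"]
            if lam:
                rep["lambda_hat"] = lam[0].shape
        reps.append(rep)

    summary: dict = {"n_replicates": len(reps)}
    s2 = np.array([r["sigma2_hat"] for r in reps])
    summary["sigma2_true"] = cfg["sigma2"]
    summary["sigma2_median"] = float(np.median(s2))
    summary["sigma2_median_bias"] = float(
        (np.median(s2) - cfg["sigma2"]) / cfg["sigma2"]
    )
    if cfg["run_signal"]:
        summary["mean_K"] = float(np.mean([r["K"] for r in reps]))
    if cfg["fit_models"]:
        fav = [r["favoured_model"] for r in reps]
        summary["model_selection_freq"] = {
            m: fav.count(m) / len(fav) for m in sorted(set(fav))
        }
        lams = [r["lambda_hat"] for r in reps if "lambda_hat" in r]
        if lams:
            summary["mean_lambda"] = float(np.mean(lams))
    if cfg["mode"] == "family" and cfg["run_macrocaic"]:
        sig = [r["macrocaic_significant"] for r in reps]
        summary["macrocaic_significant_rate"] = sum(sig) / len(sig)
    return {"config": cfg, "seed": seed, "replicates": reps, "summary": summary}
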