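"""Seeded generators of trees, traits, strain tables, and KO matrices.

The generators emulate the statistical structure of a curated strain
phenotype database with an associated 16S phylogeny and genome-linked KO
profiles, so that every pipeline stage can be exercised with known ground
truth: Yule (pure-birth) trees; continuous traits evolved under Brownian
motion or drawn as white noise; binary traits from a Brownian-threshold
model or as uniform shuffles; strain records whose pH/salinity preferences
are reported as an optimum or only as a (min, max) range; and KO
presence/absence matrices in which a chosen subset of KOs has a planted
logistic dependence on a trait optimum.

Default study-scale sizes mirror the curated database the package targets:
5,130 strain records, 4,188 of them on the tree, 754 genome-linked strains
and 6,889 KO columns (see ``FULL_SCALE``).  All outputs are bit-reproducible
from (parameters, seed), and the writers emit exactly the file formats the
parsing modules read.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional

import dendropy
import numpy as np
import pandas as pd

from .phylo import Phylogeny, TipTraitMap
from .signal import simulate_bm, threshold_binarize
from .trait_db import EnvRange, StrainRecord, write_strain_table

__all__ = [
    "FULL_SCALE",
    "simulate_tree",
    "simulate_trait",
    "simulate_strain_table",
    "simulate_ko_matrix",
    "simulate_hit_table",
    "write_fixture_dir",
]

FULL_SCALE = {
    "n_strains": 5130,
    "n_tree_tips": 4188,
    "n_genomes": 754,
    "n_kos": 6889,
}

_SHAPE_P = {"rod": 0.66, "coccus": 0.20, "spiral": 0.05, "filament": 0.05,
            "other": 0.04}
_HABITAT_P = {"soil": 0.30, "marine": 0.25, "plant": 0.15, "freshwater": 0.10,
              "host": 0.10, "other": 0.10}
_OXYGEN_P = {"aerobe": 0.55, "anaerobe": 0.15, "facultative": 0.25,
             "microaerophile": 0.05}
_AGG_P = {"none": 0.70, "chain": 0.15, "clump": 0.10, "other": 0.05}


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def simulate_tree(n_tips: int, birth_rate: float = 1.0, seed=None) -> Phylogeny:
    """Yule (pure-birth) tree with ``n_tips`` extant tips.

    Starting from two lineages, the waiting time to the next split with k
    extant lineages is Exponential(k * birth_rate) and a uniformly chosen
    lineage splits; the tree is cut at the moment the (n+1)-th lineage
    would arise, so the expected root-to-tip depth is
    sum_{k=2..n} 1 / (k * birth_rate).  Tips are labeled S0001... in tree
    order.
    """
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = _rng(seed)

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    active = []
    for _ in range(2):
        child = dendropy.Node()
        child.edge.length = 0.0
        root.add_child(child)
        active.append(child)
    for k in range(2, n_tips + 1):
        dt = rng.exponential(1.0 / (k * birth_rate))
        for node in active:
            node.edge.length += dt
        if k == n_tips:
            break
        idx = rng.integers(len(active))
        parent = active.pop(int(idx))
        for _ in range(2):
            child = dendropy.Node()
            child.edge.length = 0.0
            parent.add_child(child)
            active.append(child)
    width = max(4, len(str(n_tips)))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = taxa.new_taxon(label=f"S{i:0{width}d}")
    return Phylogeny(tree)


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def simulate_trait(
    tree: Phylogeny,
    kind: str,
    *,
    sigma2: float = 1.0,
    sd: float = 1.0,
    prevalence: float = 0.5,
    seed=None,
    name: Optional[str] = None,
) -> TipTraitMap:
    """One synthetic tip trait under a named generative model.

    kinds: ``"bm"`` (Brownian motion, variance rate ``sigma2``),
    ``"white_noise"`` (i.i.d. Normal(0, sd^2), no tree structure),
    ``"threshold"`` (Brownian latent trait cut so that round(prevalence*n)
    tips are 1), ``"shuffle"`` (binary, round(prevalence*n) ones placed
    uniformly at random).
    """
    rng = _rng(seed)
    labels = tree.tip_labels
    n = len(labels)
    name = name or kind
    if kind == "bm":
        t = simulate_bm(tree, sigma2=sigma2, seed=rng, name=name)
        t.meta["model"] = "bm"
        return t
    if kind == "white_noise":
        vals = rng.normal(0.0, sd, size=n)
        return TipTraitMap(dict(zip(labels, map(float, vals))), name=name,
                           kind="continuous", meta={"model": "white_noise"})
    k_ones = int(round(prevalence * n))
    if not 0 < k_ones < n:
        raise ValueError(f"prevalence {prevalence} leaves no variation at n={n}")
    if kind == "threshold":
        latent = simulate_bm(tree, sigma2=sigma2, seed=rng)
        t = threshold_binarize(latent.values, k_ones, name=name)
        t.meta["model"] = "threshold"
        return t
    if kind == "shuffle":
        vals = np.zeros(n)
        vals[rng.choice(n, size=k_ones, replace=False)] = 1.0
        return TipTraitMap(dict(zip(labels, map(float, vals))), name=name,
                           kind="binary", meta={"model": "shuffle"})
    raise ValueError(f"unknown trait kind {kind!r}")


# ---------------------------------------------------------------------------
# strain tables
# ---------------------------------------------------------------------------

def simulate_strain_table(
    tree: Phylogeny,
    *,
    range_only_fraction: float = 0.3,
    range_halfwidth_ph: float = 1.0,
    range_halfwidth_salt: float = 1.0,
    missingness: Optional[Mapping[str, float]] = None,
    seed=None,
) -> tuple[list[StrainRecord], pd.DataFrame]:
    """Strain records keyed by the tree's tip labels, with latent truth.

    Latent pH optima are uniform(4, 9) (the neutrophile-dominated spread of
    curated strain descriptions); salinity optima are lognormal(0.5, 1) in
    % NaCl w/v.  A ``range_only_fraction`` of records report each optimum
    only as a symmetric (min, max) range around the latent value, so the
    midpoint rule must be applied to recover it.  ``missingness`` maps
    field names to per-field drop probabilities.  Returns the records and a
    DataFrame of the latent values.
    """
    if not 0.0 <= range_only_fraction <= 1.0:
        raise ValueError("range_only_fraction must be in [0,1]")
    rng = _rng(seed)
    missingness = dict(missingness or {})
    labels = tree.tip_labels
    n = len(labels)

    ph = rng.uniform(4.0, 9.0, size=n)
    salt = rng.lognormal(mean=0.5, sigma=1.0, size=n)
    salt = np.minimum(salt, 30.0)
    temp = rng.normal(30.0, 8.0, size=n)
    range_only = rng.random(n) < range_only_fraction

    def pick(dist: Mapping[str, float]) -> str:
        cats = list(dist)
        return cats[rng.choice(len(cats), p=np.array(list(dist.values())))]

    def tristate(p_pos: float) -> str:
        return "positive" if rng.random() < p_pos else "negative"

    def drop(fld: str) -> bool:
        return rng.random() < missingness.get(fld, 0.0)

    records = []
    latent_rows = []
    for i, sid in enumerate(labels):
        rec = StrainRecord(
            strain_id=sid,
            year=int(rng.integers(2004, 2015)),
            doi=f"10.1099/ijs.0.{rng.integers(10**6):06d}-0",
            gram_stain=None if drop("gram_stain") else tristate(0.45),
            cell_length_um=None if drop("cell_length_um")
            else float(np.round(rng.lognormal(0.6, 0.4), 2)),
            cell_width_um=None if drop("cell_width_um")
            else float(np.round(rng.lognormal(-0.4, 0.3), 2)),
            shape=None if drop("shape") else pick(_SHAPE_P),
            aggregation=None if drop("aggregation") else pick(_AGG_P),
            motility=None if drop("motility") else tristate(0.6),
            flagella=None if drop("flagella") else tristate(0.55),
            spore=None if drop("spore") else tristate(0.25),
            pigment=None if drop("pigment") else tristate(0.4),
            habitat=None if drop("habitat") else pick(_HABITAT_P),
            oxygen=None if drop("oxygen") else pick(_OXYGEN_P),
            gc_content=None if drop("gc_content")
            else float(np.round(rng.uniform(25, 75), 1)),
            rrna16s_accession=f"SYN16S{i:05d}",
        )
        if not drop("ph"):
            if range_only[i]:
                rec.ph_range = EnvRange(
                    min=max(0.0, ph[i] - range_halfwidth_ph),
                    max=min(14.0, ph[i] + range_halfwidth_ph),
                )
            else:
                rec.ph_range = EnvRange(optimum=float(np.round(ph[i], 2)))
        if not drop("salt"):
            if range_only[i]:
                rec.salt_range = EnvRange(
                    min=max(0.0, salt[i] - range_halfwidth_salt),
                    max=salt[i] + range_halfwidth_salt,
                )
            else:
                rec.salt_range = EnvRange(optimum=float(np.round(salt[i], 3)))
        if not drop("temp"):
            rec.temp_range = EnvRange(optimum=float(np.round(temp[i], 1)))
        records.append(rec)
        latent_rows.append(
            {"strain_id": sid, "ph_optimum": ph[i], "salt_optimum": salt[i],
             "temp_optimum": temp[i], "range_only": bool(range_only[i])}
        )
    return records, pd.DataFrame(latent_rows).set_index("strain_id")


# ---------------------------------------------------------------------------
# KO matrices
# ---------------------------------------------------------------------------

def simulate_ko_matrix(
    optima: pd.Series | Mapping[str, float],
    n_kos: int,
    n_planted: int = 0,
    beta1: float = 2.0,
    beta0: float = 0.0,
    seed=None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Strains x KOs presence/absence with a planted logistic signal.

    Planted KOs (ids K99001...) are present with probability
    expit(beta0 + beta1 * (optimum - mean optimum)); centering keeps beta0
    interpretable as the baseline log-odds of presence regardless of the
    trait's scale.  Alternating planted KOs flip the slope's sign so both
    directions are represented.  Null KOs are Bernoulli(p) with p drawn
    uniform(0.05, 0.95) per KO, independent of the trait.  Returns the
    matrix and the planted ground truth (ko_id, beta1, sign).
    """
    if n_planted > n_kos:
        raise ValueError("n_planted cannot exceed n_kos")
    optima = pd.Series(dict(optima) if not isinstance(optima, pd.Series) else optima)
    optima = optima.dropna().astype(float)
    rng = _rng(seed)
    strains = list(optima.index)
    n = len(strains)
    x = optima.to_numpy() - optima.to_numpy().mean()

    cols = {}
    truth = []
    n_null = n_kos - n_planted
    null_p = rng.uniform(0.05, 0.95, size=n_null)
    null_draws = rng.random((n, n_null)) < null_p
    for j in range(n_null):
        cols[f"K{j + 1:05d}"] = null_draws[:, j].astype(np.int8)
    for j in range(n_planted):
        b1 = beta1 if j % 2 == 0 else -beta1
        p = 1.0 / (1.0 + np.exp(-(beta0 + b1 * x)))
        ko = f"K{99001 + j:05d}"
        cols[ko] = (rng.random(n) < p).astype(np.int8)
        truth.append({"ko_id": ko, "beta1": b1, "sign": "+" if b1 > 0 else "-"})
    mat = pd.DataFrame(cols, index=strains)
    return mat, truth


def simulate_hit_table(
    strains: list[str],
    linked_fraction: float = 0.3,
    seed=None,
) -> pd.DataFrame:
    """A 16S-vs-genome hit table exercising the similarity filter.

    A ``linked_fraction`` of strains get a passing best hit (identity in
    (99, 100]%, coverage in (95, 100]%); the rest get a decoy hit that
    fails at least one strict threshold.
    """
    rng = _rng(seed)
    rows = []
    for i, sid in enumerate(strains):
        gid = f"G{i:05d}"
        if rng.random() < linked_fraction:
            ident = rng.uniform(99.05, 100.0)
            cov = rng.uniform(0.955, 1.0)
        elif rng.random() < 0.5:
            ident = rng.uniform(90.0, 99.0)  # identity fails (<= 99)
            cov = rng.uniform(0.955, 1.0)
        else:
            ident = rng.uniform(99.05, 100.0)
            cov = rng.uniform(0.5, 0.95)  # coverage fails (<= 0.95)
        qlen = 1500
        rows.append(
            {"query_id": sid, "subject_id": gid,
             "pct_identity": round(ident, 3),
             "alignment_length": int(round(cov * qlen)),
             "query_length": qlen}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fixture writer
# ---------------------------------------------------------------------------

def write_fixture_dir(
    outdir,
    n_tips: int = 200,
    n_kos: int = 500,
    n_planted: int = 5,
    beta1: float = 2.0,
    seed: int = 0,
) -> dict:
    """Emit a complete synthetic study into ``outdir``.

    Files written: strains.tsv (phenotype table), tree.nwk, hits.tsv (16S
    hit table), ko_matrix.tsv, tcdb_ko.txt (planted KOs double as the
    transporter list so classification paths are exercised), and
    ground_truth.json.  Returns the manifest.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    s_tree, s_table, s_hits, s_ko = (
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4)
    )
    tree = simulate_tree(n_tips, seed=s_tree)
    records, latent = simulate_strain_table(tree, seed=s_table)
    hits = simulate_hit_table(tree.tip_labels, seed=s_hits)
    mat, truth = simulate_ko_matrix(
        latent["ph_optimum"], n_kos=n_kos, n_planted=n_planted,
        beta1=beta1, seed=s_ko,
    )
    with open(out / "tree.nwk", "w") as fh:
        fh.write(tree.to_newick() + "\n")
    write_strain_table(records, out / "strains.tsv")
    hits.to_csv(out / "hits.tsv", sep="\t", index=False)
    mat.to_csv(out / "ko_matrix.tsv", sep="\t", index_label="strain_id")
    with open(out / "tcdb_ko.txt", "w") as fh:
        for t in truth:
            fh.write(t["ko_id"] + "\n")
    manifest = {
        "seed": seed, "n_tips": n_tips, "n_kos": n_kos,
        "n_planted": n_planted, "beta1": beta1,
        "planted": truth,
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
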