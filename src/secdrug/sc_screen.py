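"""Single-cell "double-hit" screen and treatment-induced cluster erosion.

The double-hit idea: a secondary drug is most promising when (a) it ranks
highly in the pharmacogenomic secDrug screen and (b) single-cell expression
shows its target pathway active in the subclones of concern (drug-resistant,
stem-like, EMT). This module scores per-cluster marker-gene programs on
log-normalized counts, combines program coverage with the secDrug rank into
a single double-hit score, and tests whether treatment erodes a cluster
(a significant post-treatment drop in its cell proportion — the computational
proxy for "a cluster disappearing from the embedding").

Cells live in :class:`anndata.AnnData` objects with raw counts in ``.X``
(kept in ``layers["counts"]`` after normalization) and ``cluster`` /
``condition`` columns in ``.obs``. Clustering itself is an upstream input;
a deterministic k-means-on-PCs baseline is provided for fixture generation
only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import yaml
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

TARGET_DEPTH = 10_000.0


@dataclass
class GeneProgram:
    """A named marker-gene set with per-gene direction (+1 up, -1 down)."""

    name: str
    genes: list[str]
    directions: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("program needs at least one gene")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in program")
        for g in self.genes:
            self.directions.setdefault(g, 1)
            if self.directions[g] not in (1, -1):
                raise ValueError(f"direction for {g} must be +1 or -1")

    @property
    def up_genes(self) -> list[str]:
        return [g for g in self.genes if self.directions[g] == 1]


def read_programs_yaml(path) -> list[GeneProgram]:
    """Load gene programs from YAML: a list of {name, genes, down: [...]}. """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    programs = []
    for rec in raw:
        down = set(rec.get("down", []))
        genes = list(rec["genes"])
        dirs = {g: (-1 if g in down else 1) for g in genes}
        programs.append(GeneProgram(rec["name"], genes, dirs))
    return programs


def _dense(x) -> np.ndarray:
    return x.toarray() if sparse.issparse(x) else np.asarray(x)


def read_cell_matrix(matrix_path, barcodes_path=None, features_path=None,
                     metadata_path=None) -> ad.AnnData:
    """Read counts from an MTX triplet (genes x cells) or a dense CSV
    (cells as rows, genes as columns), plus optional cell metadata CSV with
    columns barcode, cluster, condition."""
    from scipy.io import mmread

    path = str(matrix_path)
    if path.endswith(".mtx"):
        if barcodes_path is None or features_path is None:
            raise ValueError("MTX input needs barcodes and features files")
        m = sparse.csr_matrix(mmread(path).T)  # stored genes x cells
        barcodes = pd.read_csv(barcodes_path, header=None, sep="\t")[0].astype(str)
        features = pd.read_csv(features_path, header=None, sep="\t")[0].astype(str)
        adata = ad.AnnData(
            X=m,
            obs=pd.DataFrame(index=barcodes),
            var=pd.DataFrame(index=features),
        )
    else:
        df = pd.read_csv(path, index_col=0)
        adata = ad.AnnData(df)
    if adata.var_names.duplicated().any():
        raise ValueError("duplicate gene identifiers")
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path).set_index("barcode")
        meta.index = meta.index.astype(str)
        for col in ("cluster", "condition", "sample_id"):
            if col in meta.columns:
                adata.obs[col] = meta.reindex(adata.obs_names)[col].astype(str)
    return adata


def normalize_counts(adata: ad.AnnData) -> ad.AnnData:
    """Depth-normalize to 10,000 counts per cell, then log(1 + x).

    Raw counts are preserved in ``layers["counts"]``. Zero-depth cells are
    dropped with a warning; an all-zero matrix is an error.
    """
    counts = adata.X
    depth = np.asarray(counts.sum(axis=1)).ravel()
    if depth.sum() == 0:
        raise ValueError("all-zero count matrix")
    keep = depth > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-depth cells", stacklevel=2)
    out = adata[keep].copy()
    counts = out.X
    depth = np.asarray(counts.sum(axis=1)).ravel()
    out.layers["counts"] = counts.copy()
    if sparse.issparse(counts):
        scaled = sparse.diags(TARGET_DEPTH / depth) @ counts
        scaled.data = np.log1p(scaled.data)
        out.X = sparse.csr_matrix(scaled)
    else:
        out.X = np.log1p(np.asarray(counts) * (TARGET_DEPTH / depth)[:, None])
    return out


def score_program(
    adata: ad.AnnData,
    program: GeneProgram,
    positivity_fraction: float = 0.5,
    cluster_key: str = "cluster",
) -> pd.DataFrame:
    """Per-cluster program score and positive-cell fraction.

    Per-cell score: mean over the program genes present in the matrix of the
    signed log-normalized expression (down-direction genes negated). A cell
    is *positive* when more than ``positivity_fraction`` of the program's
    up-direction genes have a nonzero raw count — a dropout-robust reading of
    "the pathway is expressed". Returns a DataFrame indexed by cluster with
    mean_score, fraction_positive and n_cells.
    """
    if cluster_key not in adata.obs:
        raise ValueError(f"missing obs column {cluster_key!r}")
    if adata.obs[cluster_key].isna().any():
        raise ValueError("cluster labels must be non-empty for all cells")
    present = [g for g in program.genes if g in adata.var_names]
    if not present:
        raise ValueError(f"no gene of program {program.name!r} present in matrix")
    absent = set(program.genes) - set(present)
    if absent:
        warnings.warn(
            f"program {program.name!r}: {len(absent)} genes absent ({sorted(absent)})",
            stacklevel=2,
        )
    expr = _dense(adata[:, present].X)
    signs = np.array([program.directions[g] for g in present], dtype=float)
    cell_score = (expr * signs).mean(axis=1)

    up_present = [g for g in program.up_genes if g in adata.var_names]
    counts = adata.layers["counts"] if "counts" in adata.layers else adata.X
    if up_present:
        sub = _dense(adata[:, up_present].layers["counts"]
                     if "counts" in adata.layers else adata[:, up_present].X)
        detected = (sub > 0).mean(axis=1)
        positive = detected > positivity_fraction
    else:
        positive = np.zeros(adata.n_obs, dtype=bool)

    df = pd.DataFrame(
        {
            "cluster": adata.obs[cluster_key].to_numpy(),
            "score": cell_score,
            "positive": positive,
        }
    )
    out = df.groupby("cluster", observed=True).agg(
        mean_score=("score", "mean"),
        fraction_positive=("positive", "mean"),
        n_cells=("score", "size"),
    )
    out.insert(0, "program", program.name)
    return out


def double_hit(
    ranking,
    screens: dict[str, pd.DataFrame],
    flagged_clusters=(),
) -> pd.DataFrame:
    """Combine secDrug rank with single-cell target-pathway coverage.

    ``secdrug_rank_score = 1 - (rank - 1)/K`` maps rank 1..K onto (0, 1];
    ``target_coverage`` is the cell-weighted mean fraction_positive of the
    drug's target-pathway program over the flagged clusters (all clusters,
    with a warning, when none are flagged). ``double_hit`` is their product,
    and the table is sorted by it, descending.
    """
    table = ranking.table if hasattr(ranking, "table") else ranking
    k_total = len(table)
    flagged = set(flagged_clusters)
    rows = []
    for _, rec in table.iterrows():
        drug = rec["drug_id"]
        if drug not in screens:
            continue
        screen = screens[drug]
        if flagged:
            sel = screen.loc[screen.index.intersection(flagged)]
        else:
            sel = screen
        if not flagged:
            warnings.warn(
                "no flagged clusters: coverage computed over all clusters",
                stacklevel=2,
            )
        if sel.empty or sel["n_cells"].sum() == 0:
            coverage = 0.0
        else:
            coverage = float(
                np.average(sel["fraction_positive"], weights=sel["n_cells"])
            )
        rank_score = 1.0 - (rec["rank"] - 1) / k_total
        rows.append(
            {
                "drug_id": drug,
                "rank": int(rec["rank"]),
                "secdrug_rank_score": rank_score,
                "target_coverage": coverage,
                "double_hit": rank_score * coverage,
            }
        )
    out = pd.DataFrame(
        rows, columns=["drug_id", "rank", "secdrug_rank_score",
                       "target_coverage", "double_hit"]
    )
    return out.sort_values(
        ["double_hit", "drug_id"], ascending=[False, True]
    ).reset_index(drop=True)


def _cluster_labels(obj, cluster_key: str) -> pd.Series:
    if isinstance(obj, ad.AnnData):
        return obj.obs[cluster_key].astype(str)
    return pd.Series(obj).astype(str)


def detect_cluster_erosion(
    pre,
    post,
    cluster_key: str = "cluster",
    alpha: float = 0.05,
    fold: float = 0.5,
) -> pd.DataFrame:
    """Flag clusters whose cell proportion collapses after treatment.

    Accepts AnnData objects (with a shared ``cluster`` label space) or bare
    label arrays. Per cluster, a two-sided Fisher exact test on the 2x2
    table [in-cluster vs out] x [pre vs post], Benjamini-Hochberg adjusted
    across clusters; a cluster is *eroded* when its post proportion is at
    most ``fold`` times its pre proportion and the adjusted p-value is below
    ``alpha``.
    """
    pre_lab = _cluster_labels(pre, cluster_key)
    post_lab = _cluster_labels(post, cluster_key)
    n_pre, n_post = len(pre_lab), len(post_lab)
    clusters = sorted(set(pre_lab) | set(post_lab))
    rows = []
    for cl in clusters:
        a = int((pre_lab == cl).sum())
        c = int((post_lab == cl).sum())
        if a == 0 and c == 0:
            continue
        _, p = stats.fisher_exact([[a, n_pre - a], [c, n_post - c]])
        rows.append(
            {
                "cluster": cl,
                "n_pre": a,
                "n_post": c,
                "prop_pre": a / n_pre,
                "prop_post": c / n_post,
                "p": p,
            }
        )
    out = pd.DataFrame(rows).set_index("cluster")
    out["relative_change"] = np.where(
        out["prop_pre"] > 0, out["prop_post"] / out["prop_pre"] - 1.0, np.inf
    )
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    out["eroded"] = (out["prop_post"] <= fold * out["prop_pre"]) & (out["p_adj"] < alpha)
    return out


def transfer_labels(
    pre: ad.AnnData, post: ad.AnnData, cluster_key: str = "cluster"
) -> ad.AnnData:
    """Assign post-treatment cells to pre-defined clusters by nearest centroid.

    Distances are weighted Euclidean on per-gene standardized (pre-data
    statistics) log-normalized expression, with each gene weighted by its
    between- over within-cluster variance ratio in the pre data — so a
    handful of discriminative marker genes is not drowned out by hundreds of
    uninformative ones. Returns a copy of ``post`` with ``cluster`` set.
    """
    shared = pre.var_names.intersection(post.var_names)
    if len(shared) == 0:
        raise ValueError("no shared genes between conditions")
    pre_x = _dense(pre[:, shared].X)
    post_x = _dense(post[:, shared].X)
    mu = pre_x.mean(axis=0)
    sd = pre_x.std(axis=0)
    sd[sd == 0] = 1.0
    pre_z = (pre_x - mu) / sd
    post_z = (post_x - mu) / sd
    labels = pre.obs[cluster_key].astype(str)
    names = sorted(labels.unique())
    cmat = np.vstack([pre_z[(labels == cl).to_numpy()].mean(axis=0) for cl in names])
    within = np.vstack(
        [pre_z[(labels == cl).to_numpy()].var(axis=0) for cl in names]
    ).mean(axis=0)
    weight = cmat.var(axis=0) / (within + 1e-6)
    d2 = (((post_z[:, None, :] - cmat[None, :, :]) ** 2) * weight[None, None, :]).sum(axis=2)
    out = post.copy()
    out.obs[cluster_key] = [names[i] for i in d2.argmin(axis=1)]
    return out


def baseline_clusters(
    adata: ad.AnnData, n_clusters: int = 4, n_pcs: int = 50, seed: int = 0
) -> pd.Series:
    """Deterministic k-means-on-PCs baseline clustering (fixture use only)."""
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    x = _dense(adata.X)
    n_pcs = min(n_pcs, min(x.shape) - 1)
    pcs = PCA(n_components=n_pcs, random_state=seed).fit_transform(x)
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed).fit(pcs)
    return pd.Series(km.labels_.astype(str), index=adata.obs_names, name="cluster")
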