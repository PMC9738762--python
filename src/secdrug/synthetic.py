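"""Seeded generators for every input the pipeline consumes, with truth manifests.

Each generator emulates the statistical structure its downstream stage
assumes and records the planted ground truth in a :class:`GeneratorManifest`
so that recovery tests read truth only from the manifest:

* :func:`simulate_pgx_panel` — a GDSC1000-like log-normal IC50 panel with a
  resistant cell-line subgroup for the primary drug and planted secondary
  drugs that are selectively potent in that subgroup;
* :func:`simulate_combination` — combination measurements with a planted
  combination index, obtained by inverting the CI equation for the fraction
  affected at each dose pair (bisection on a strictly decreasing function);
* :func:`simulate_sc_counts` — negative-binomial single-cell counts with
  cluster-specific marker programs (EMT, stemness, NAD-salvage/PSAT1-high)
  and a post-treatment composition shift eroding one cluster;
* :func:`simulate_cohort` — patient expression with planted
  recurrence-associated genes, a subset of which is reversed in a paired
  pre/post treatment contrast.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import optimize

from .pgx_io import DoseResponsePanel
from .synergy import DEFAULT_EPS, CombinationMeasurement, MedianEffectFit

# Per-tissue line counts of the genito-urinary panel subset the tissue-filter
# worked example reconstructs (sums to 136).
GU_TISSUE_COUNTS = {
    "breast": 52, "cervix": 14, "endometrium": 11, "ovary": 45,
    "prostate": 8, "testis": 3, "vulva": 3,
}

#: drug -> (target, target pathway) for the named drugs the generator plants
DRUG_TARGETS = {
    "FK866": ("NAMPT", "NAD+ salvage pathway"),
    "YM155": ("BIRC5", "Apoptosis regulation"),
    "MK-2206": ("AKT1, AKT2", "PI3K/MTOR signaling"),
    "TAK-715": ("p38 MAPK", "JNK and p38 signaling"),
    "RDEA119": ("MEK1, MEK2", "ERK MAPK signaling"),
    "XAV939": ("TNKS1, TNKS2", "WNT signaling"),
    "docetaxel": ("Microtubules", "Mitosis"),
}

#: marker programs of the planted subclones (gene -> log2-fold elevation;
#: negative values are depletions, e.g. E-cadherin loss in EMT)
DEFAULT_CLUSTER_PROGRAMS = {
    "EMT": {
        "VIM": 2.0, "CDH2": 2.0, "FN1": 2.0, "S100A4": 2.0, "SNAI1": 2.0,
        "SNAI2": 2.0, "TWIST1": 2.0, "ZEB1": 2.0, "CDH1": -2.0,
    },
    "stem": {
        "CD44": 2.0, "HES1": 2.0, "CXCL8": 2.0, "PLAU": 2.0, "PLAUR": 2.0,
        "CDH11": 2.0, "CDK1": 2.0,
    },
    "PSAT1_high": {"NAMPT": 2.0, "NAPRT": 2.0, "PSAT1": 2.0},
    "base": {},
}

DEFAULT_CELLS_PER_CLUSTER = {"base": 500, "EMT": 150, "stem": 150, "PSAT1_high": 200}

#: default erosion: the PSAT1-high cluster collapses from 20% to 1%
DEFAULT_EROSION = {"PSAT1_high": 0.01}

#: recurrence-associated genes planted in the patient cohort
DEFAULT_SIGNATURE_GENES = (
    "LTB4R", "IFITM3", "TMEM120B", "C1S", "FAS", "LGALS3BP", "MAT2A",
)
#: subset reversed by treatment (the reverse-match ground truth)
DEFAULT_TREATMENT_OVERLAP = ("LTB4R", "IFITM3", "TMEM120B")


@dataclass
class GeneratorManifest:
    """Planted ground truth of one simulation, keyed by public identifiers."""

    scenario: str
    seed: int
    truth: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def make_tissue_annotations(tissue_counts=None, prefix: str = "CL") -> pd.DataFrame:
    """Build a cell-line annotation table with exact per-tissue counts."""
    counts = dict(tissue_counts or GU_TISSUE_COUNTS)
    rows = []
    i = 0
    for tissue, n in counts.items():
        for _ in range(int(n)):
            i += 1
            rows.append({"cell_line_id": f"{prefix}{i:04d}", "tissue": tissue,
                         "subtype": ""})
    return pd.DataFrame(rows).set_index("cell_line_id")


def example_drug_annotations() -> pd.DataFrame:
    """Drug -> target / target-pathway table for the named generator drugs."""
    rows = [
        {"drug_id": d, "target": t, "target_pathway": p}
        for d, (t, p) in DRUG_TARGETS.items()
    ]
    return pd.DataFrame(rows).set_index("drug_id")


def simulate_pgx_panel(
    n_lines: int = 136,
    n_drugs: int = 265,
    resistant_fraction: float = 0.25,
    shift_log10: float = 1.5,
    n_planted_secdrugs: int = 1,
    missing_rate: float = 0.05,
    sigma_log10: float = 0.3,
    primary_drug_id: str = "docetaxel",
    seed: int = 0,
) -> tuple[DoseResponsePanel, GeneratorManifest]:
    """Simulate a drug x cell-line IC50 panel with planted structure.

    log10 IC50 for drug k is Normal(mu_k, sigma) with mu_k ~ Uniform(1, 3)
    (10 nM - 1 uM scale). A ``resistant_fraction`` subgroup of lines gets the
    primary drug shifted +``shift_log10`` (less sensitive); planted secondary
    drugs are shifted -1.0 in exactly those lines (selectively potent).
    Entries go missing uniformly at ``missing_rate``. Tissue labels are drawn
    with the genito-urinary panel proportions.
    """
    if not 0 < resistant_fraction < 1:
        raise ValueError("resistant_fraction must be in (0, 1)")
    if n_planted_secdrugs >= n_drugs:
        raise ValueError("n_planted_secdrugs must be < n_drugs")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)

    line_ids = [f"CL{i + 1:04d}" for i in range(n_lines)]
    planted_names = [d for d in DRUG_TARGETS if d != primary_drug_id]
    planted = [
        planted_names[i] if i < len(planted_names) else f"planted{i + 1}"
        for i in range(n_planted_secdrugs)
    ]
    fillers = [f"D{i + 1:04d}" for i in range(n_drugs - 1 - n_planted_secdrugs)]
    drug_ids = [primary_drug_id] + planted + fillers

    n_resistant = int(round(resistant_fraction * n_lines))
    resistant_idx = rng.choice(n_lines, size=n_resistant, replace=False)
    resistant_mask = np.zeros(n_lines, dtype=bool)
    resistant_mask[resistant_idx] = True

    mu = rng.uniform(1.0, 3.0, size=len(drug_ids))
    log_ic50 = rng.normal(mu[:, None], sigma_log10, size=(len(drug_ids), n_lines))
    log_ic50[0, resistant_mask] += shift_log10
    for j in range(1, 1 + n_planted_secdrugs):
        log_ic50[j, resistant_mask] -= 1.0
    values = 10.0 ** log_ic50
    if missing_rate > 0:
        values[rng.random(values.shape) < missing_rate] = np.nan

    tissues = list(GU_TISSUE_COUNTS)
    probs = np.array(list(GU_TISSUE_COUNTS.values()), dtype=float)
    probs /= probs.sum()
    ann = pd.DataFrame(
        {"tissue": rng.choice(tissues, size=n_lines, p=probs), "subtype": ""},
        index=pd.Index(line_ids, name="cell_line_id"),
    )
    panel = DoseResponsePanel(
        pd.DataFrame(values, index=drug_ids, columns=line_ids), annotations=ann
    )
    manifest = GeneratorManifest(
        scenario="pgx_panel",
        seed=seed,
        truth={
            "primary_drug_id": primary_drug_id,
            "planted_secdrugs": planted,
            "resistant_lines": [line_ids[i] for i in sorted(resistant_idx)],
        },
        params={
            "n_lines": n_lines, "n_drugs": n_drugs,
            "resistant_fraction": resistant_fraction,
            "shift_log10": shift_log10, "missing_rate": missing_rate,
            "sigma_log10": sigma_log10,
        },
    )
    return panel, manifest


def simulate_combination(
    fit1_true: MedianEffectFit | tuple,
    fit2_true: MedianEffectFit | tuple,
    dose_pairs,
    ci_true: float = 0.25,
    fa_noise_sd: float = 0.0,
    seed: int = 0,
    eps: float = DEFAULT_EPS,
) -> tuple[CombinationMeasurement, GeneratorManifest]:
    """Combination measurements carrying a planted combination index.

    For each dose pair, the fraction affected solving
    ``d1/Dx1(fa) + d2/Dx2(fa) = ci_true`` is found by bisection on
    fa in (eps, 1-eps) — the left side is strictly decreasing in fa, so the
    root is unique when it exists; pairs with no root in the bracket are
    rejected with a message. Gaussian noise (sd ``fa_noise_sd``) is added
    and clipped back into (eps, 1-eps).
    """
    if ci_true <= 0:
        raise ValueError("ci_true must be > 0")

    def as_fit(f, name):
        if isinstance(f, MedianEffectFit):
            return f
        dm, m = f
        return MedianEffectFit(name, float(dm), float(m), 1.0, 0)

    f1 = as_fit(fit1_true, "drug1")
    f2 = as_fit(fit2_true, "drug2")
    rng = np.random.default_rng(seed)
    rows, fa_truth, rejected = [], [], []
    for d1, d2 in dose_pairs:
        if d1 <= 0 and d2 <= 0:
            raise ValueError("each pair needs at least one positive dose")

        def gap(fa, d1=d1, d2=d2):
            return (
                (d1 / float(f1.dx(fa)) if d1 > 0 else 0.0)
                + (d2 / float(f2.dx(fa)) if d2 > 0 else 0.0)
                - ci_true
            )

        lo, hi = eps, 1.0 - eps
        if gap(lo) < 0 or gap(hi) > 0:
            rejected.append(
                f"(d1={d1:g}, d2={d2:g}): no fa in ({eps}, {1 - eps}) "
                f"reaches CI={ci_true}"
            )
            continue
        fa = optimize.brentq(gap, lo, hi, xtol=1e-12)
        fa_truth.append(fa)
        fa_obs = fa + (rng.normal(0.0, fa_noise_sd) if fa_noise_sd > 0 else 0.0)
        rows.append({"d1": float(d1), "d2": float(d2),
                     "fa": float(np.clip(fa_obs, eps, 1.0 - eps))})
    if not rows:
        raise ValueError("all dose pairs rejected: " + "; ".join(rejected))
    combo = CombinationMeasurement(pd.DataFrame(rows), fixed_ratio=True)
    manifest = GeneratorManifest(
        scenario="combination",
        seed=seed,
        truth={"ci_true": ci_true, "fa_true": fa_truth, "rejected_pairs": rejected},
        params={
            "Dm1": f1.Dm, "m1": f1.m, "Dm2": f2.Dm, "m2": f2.m,
            "fa_noise_sd": fa_noise_sd,
        },
    )
    return combo, manifest


def simulate_cytotoxicity(
    bottom: float = 0.0,
    top: float = 100.0,
    ic50: float = 50.0,
    hill: float = 1.2,
    doses=None,
    noise_sd_percent: float = 0.0,
    n_replicates: int = 1,
    drug_id: str = "drug",
    seed: int = 0,
):
    """Percent-survival points from a 4PL truth with additive Gaussian noise.

    Default doses: 8 log-spaced concentrations spanning ic50/30 to ic50*30.
    Returns a :class:`~secdrug.dose_response.CytotoxicityCurve` and a
    manifest holding the true parameters.
    """
    from .dose_response import CytotoxicityCurve, _four_pl

    rng = np.random.default_rng(seed)
    if doses is None:
        doses = np.geomspace(ic50 / 30.0, ic50 * 30.0, 8)
    doses = np.asarray(doses, dtype=float)
    rows = []
    for rep in range(1, n_replicates + 1):
        surv = _four_pl(doses, bottom, top, ic50, hill)
        if noise_sd_percent > 0:
            surv = surv + rng.normal(0.0, noise_sd_percent, size=doses.shape)
        rows.append(
            pd.DataFrame(
                {
                    "concentration_nM": doses,
                    "percent_survival": surv,
                    "replicate_id": rep,
                }
            )
        )
    curve = CytotoxicityCurve(drug_id, pd.concat(rows, ignore_index=True))
    manifest = GeneratorManifest(
        scenario="cytotoxicity",
        seed=seed,
        truth={"bottom": bottom, "top": top, "ic50": ic50, "hill": hill},
        params={"noise_sd_percent": noise_sd_percent, "doses": doses.tolist()},
    )
    return curve, manifest


def _nb_counts(rng, mean, dispersion):
    """Gamma-Poisson negative binomial draws with the given mean matrix."""
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_sc_counts(
    n_cells_per_cluster: dict | None = None,
    cluster_programs: dict | None = None,
    n_genes: int = 300,
    nb_dispersion: float = 0.5,
    depth_mean: float = 5000.0,
    depth_sigma: float = 0.3,
    erosion_spec: dict | None | str = "default",
    seed: int = 0,
) -> tuple[ad.AnnData, ad.AnnData, GeneratorManifest]:
    """Pre/post-treatment single-cell counts with planted subclone programs.

    Counts are negative binomial (gamma-Poisson, dispersion 0.5) around
    cluster-specific means: each cluster's program genes are elevated (or
    depleted) by the given log2-fold on top of a shared baseline abundance
    profile, and per-cell depth is LogNormal(log depth_mean, depth_sigma).
    The pre condition has the exact per-cluster cell numbers requested; the
    post condition has the same total with cluster proportions re-weighted
    per ``erosion_spec`` (cluster -> post proportion; default collapses the
    PSAT1-high cluster from 20% to 1%). ``erosion_spec=None`` leaves the
    composition unchanged in expectation.
    """
    cells = dict(n_cells_per_cluster or DEFAULT_CELLS_PER_CLUSTER)
    programs = dict(cluster_programs or DEFAULT_CLUSTER_PROGRAMS)
    if len(cells) < 2:
        raise ValueError("need >= 2 clusters")
    unknown = set(cells) - set(programs)
    if unknown:
        raise ValueError(f"clusters without a program entry: {sorted(unknown)}")
    if erosion_spec == "default":
        erosion_spec = {
            c: DEFAULT_EROSION[c] for c in DEFAULT_EROSION if c in cells
        } or None
    rng = np.random.default_rng(seed)

    named = sorted({g for prog in programs.values() for g in prog})
    if n_genes < len(named) + 10:
        raise ValueError(f"n_genes must be >= {len(named) + 10}")
    genes = named + [f"G{i + 1:04d}" for i in range(n_genes - len(named))]

    base_abundance = rng.gamma(0.6, 1.0, size=n_genes) + 1e-3
    clusters = sorted(cells)
    profile = {}
    for cl in clusters:
        p = base_abundance.copy()
        for g, lfc in programs.get(cl, {}).items():
            p[genes.index(g)] *= 2.0 ** lfc
        profile[cl] = p / p.sum()

    def draw(labels):
        depth = rng.lognormal(np.log(depth_mean), depth_sigma, size=len(labels))
        mean = np.vstack([profile[cl] for cl in labels]) * depth[:, None]
        x = _nb_counts(rng, mean, nb_dispersion).astype(np.int64)
        obs = pd.DataFrame(
            {"cluster": labels},
            index=[f"cell{i + 1:05d}" for i in range(len(labels))],
        )
        return ad.AnnData(X=x, obs=obs, var=pd.DataFrame(index=pd.Index(genes)))

    pre_labels = [cl for cl in clusters for _ in range(cells[cl])]
    total = len(pre_labels)
    pre_props = {cl: cells[cl] / total for cl in clusters}
    if erosion_spec:
        post_props = dict(pre_props)
        for cl, p_post in erosion_spec.items():
            post_props[cl] = float(p_post)
        rest = [cl for cl in clusters if cl not in erosion_spec]
        remaining = 1.0 - sum(post_props[cl] for cl in erosion_spec)
        rest_total = sum(pre_props[cl] for cl in rest)
        for cl in rest:
            post_props[cl] = remaining * pre_props[cl] / rest_total
    else:
        post_props = pre_props
    post_counts = rng.multinomial(total, [post_props[cl] for cl in clusters])
    post_labels = [cl for cl, n in zip(clusters, post_counts) for _ in range(n)]

    pre = draw(pre_labels)
    post = draw(post_labels)
    pre.obs["condition"] = "pre"
    post.obs["condition"] = "post"
    pre.obs["sample_id"] = "pre1"
    post.obs["sample_id"] = "post1"

    manifest = GeneratorManifest(
        scenario="sc_counts",
        seed=seed,
        truth={
            "eroded_clusters": sorted(erosion_spec) if erosion_spec else [],
            "cluster_programs": {c: dict(programs[c]) for c in clusters},
            "pre_composition": pre_props,
            "post_composition": post_props,
        },
        params={
            "n_cells_per_cluster": cells, "n_genes": n_genes,
            "nb_dispersion": nb_dispersion, "depth_mean": depth_mean,
        },
    )
    return pre, post, manifest


def simulate_cohort(
    n_patients: int = 100,
    recurrent_fraction: float = 0.49,
    signature_genes=DEFAULT_SIGNATURE_GENES,
    effect_log2: float = 2.0,
    noise_sd: float = 0.4,
    treatment_signature_overlap=DEFAULT_TREATMENT_OVERLAP,
    n_genes: int = 500,
    n_treatment_replicates: int = 6,
    seed: int = 0,
) -> tuple[tuple[pd.DataFrame, pd.Series], tuple[pd.DataFrame, pd.DataFrame], GeneratorManifest]:
    """Patient cohort and treatment contrast with a reversible signature.

    Patient expression is log-normal (log2 scale: Normal(mu_g, noise_sd),
    mu_g ~ Uniform(3, 8)); the signature genes are shifted +``effect_log2``
    in the recurrent patients (round(n * recurrent_fraction) of them, the
    100-patient default giving 49 recurrent vs 51 non-recurrent). The
    treatment arm draws pre/post replicates from the same baseline with the
    ``treatment_signature_overlap`` genes shifted -``effect_log2`` post —
    these overlap genes are the planted reverse-match truth.

    Returns ``((patient_expr, labels), (pre_expr, post_expr), manifest)``
    with samples as rows and genes as columns, linear expression scale.
    """
    signature_genes = list(signature_genes)
    overlap = list(treatment_signature_overlap)
    if not set(overlap) <= set(signature_genes):
        raise ValueError("overlap genes must be a subset of the signature genes")
    rng = np.random.default_rng(seed)

    genes = signature_genes + [
        f"G{i + 1:04d}" for i in range(n_genes - len(signature_genes))
    ]
    mu = rng.uniform(3.0, 8.0, size=n_genes)
    sig_idx = np.array([genes.index(g) for g in signature_genes])
    ov_idx = np.array([genes.index(g) for g in overlap], dtype=int)

    n_rec = int(round(n_patients * recurrent_fraction))
    labels = np.array(["no_BCR"] * n_patients, dtype=object)
    rec_rows = rng.choice(n_patients, size=n_rec, replace=False)
    labels[rec_rows] = "BCR"
    logx = rng.normal(mu[None, :], noise_sd, size=(n_patients, n_genes))
    logx[np.ix_(rec_rows, sig_idx)] += effect_log2
    patients = pd.DataFrame(
        2.0 ** logx,
        index=[f"patient{i + 1:03d}" for i in range(n_patients)],
        columns=genes,
    )
    label_series = pd.Series(labels, index=patients.index, name="group")

    def arm(shift_idx, shift, tag):
        lx = rng.normal(mu[None, :], noise_sd, size=(n_treatment_replicates, n_genes))
        if len(shift_idx):
            lx[:, shift_idx] += shift
        return pd.DataFrame(
            2.0 ** lx,
            index=[f"{tag}{i + 1}" for i in range(n_treatment_replicates)],
            columns=genes,
        )

    pre_expr = arm(np.array([], dtype=int), 0.0, "pre")
    post_expr = arm(ov_idx, -effect_log2, "post")

    manifest = GeneratorManifest(
        scenario="cohort",
        seed=seed,
        truth={
            "recurrent_patients": sorted(patients.index[rec_rows]),
            "signature_genes": signature_genes,
            "reverse_match_genes": overlap,
        },
        params={
            "n_patients": n_patients, "recurrent_fraction": recurrent_fraction,
            "effect_log2": effect_log2, "noise_sd": noise_sd, "n_genes": n_genes,
            "n_treatment_replicates": n_treatment_replicates,
        },
    )
    return (patients, label_series), (pre_expr, post_expr), manifest
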