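"""Synthetic two-experiment study generator.

Emulates the design the analysis assumes: two independent experiments, each
with three groups (normal diet ND, Western diet WD, WD plus cholestyramine
WD_Ch) of five mice. Microbial features (ASVs) are drawn negative-binomially
with group-dependent log-means; per-sample sequencing depth varies
lognormally and is removed again by the pipeline's relativization step.

Planted structure, with ground truth returned for recovery tests:

* ``reversed`` ASVs shift by +/- ``effect_log_fold`` under WD and revert to
  baseline under WD_Ch (the treatment restores them);
* ``treatment_only`` ASVs shift only under WD_Ch;
* ``diet_only`` ASVs shift under both WD and WD_Ch (diet effect the
  treatment does not touch);
* all remaining ASVs are identical across groups.

One reversed ASV is the *bridge*: within the treated group, one gene-like
and one phenotype-like host parameter are lognormal functions of its latent
log-abundance (rank correlation ~= ``bridge_strength``), and the other
reversed ASVs form a co-responding module around it (rank correlation ~=
``module_coupling``), the way a co-varying microbial guild appears in real
data. Module members use a moment-matched lognormal latent in place of the
Gamma mixing noise, so coupling changes neither their marginal means nor
variances. Coupling signs follow the endpoints' fold-change signs, so the
genuine associations survive the network's causality filter. Host parameters
are strictly positive (exponentiated Gaussians) so median normalization by
division is well defined.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import polygamma

from .tables import CountTable, Group, HostTable, SampleMetadata, Scale

__all__ = ["SimulationConfig", "GroundTruth", "StudyData", "generate_study", "truth_report"]

GROUPS = (Group.ND.value, Group.WD.value, Group.WD_Ch.value)
CATEGORIES = ("reversed", "treatment_only", "diet_only", "null")


@dataclass(frozen=True)
class SimulationConfig:
    n_mice_per_group: int = 5
    n_experiments: int = 2
    n_asvs: int = 200
    n_reversed: int = 14
    n_treatment_only: int = 31
    n_diet_only: int = 17
    nb_dispersion: float = 3.0  # NB size parameter k; variance = mu + mu^2/k
    baseline_log_mean: float = 5.5  # ln counts; ~51k reads over ~200 ASVs
    asv_log_sd: float = 1.5  # spread of per-ASV baseline log-means
    depth_log_sd: float = 0.25  # per-sample library-size lognormal sigma
    effect_log_fold: float = math.log(4.0)
    bridge_strength: float = 0.8  # latent rank correlation ASV -> gene/phenotype
    module_coupling: float = 0.7  # rank correlation of other reversed ASVs to the bridge
    host_factor_weight: float = 0.55  # shared metabolic-factor variance share of host params
    host_noise_sd: float = 0.3  # lognormal sd of host parameters
    host_effect: float = 0.8  # log-scale group offset of responsive host parameters
    n_phenotypes: int = 6
    n_genes: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reversed + self.n_treatment_only + self.n_diet_only > self.n_asvs:
            raise ValueError("planted ASV sets exceed n_asvs")
        if not 0.0 <= self.bridge_strength <= 1.0:
            raise ValueError("bridge_strength must be in [0, 1]")
        if self.nb_dispersion <= 0 or self.host_noise_sd <= 0:
            raise ValueError("nb_dispersion and host_noise_sd must be positive")
        if min(self.n_mice_per_group, self.n_experiments, self.n_asvs) < 1:
            raise ValueError("design sizes must be positive")
        if self.n_phenotypes < 1 or self.n_genes < 1:
            raise ValueError("need at least one phenotype and one gene")


@dataclass(frozen=True)
class GroundTruth:
    membership: pd.Series  # feature_id -> category
    bridge_asv_id: str
    bridge_gene_id: str
    bridge_phenotype_id: str
    group_log_means: pd.DataFrame  # features x groups, ln of NB mean (before depth)

    def features(self, category: str) -> list[str]:
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        return list(self.membership.index[self.membership == category])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "membership": self.membership.to_dict(),
            "bridge_asv_id": self.bridge_asv_id,
            "bridge_gene_id": self.bridge_gene_id,
            "bridge_phenotype_id": self.bridge_phenotype_id,
            "group_log_means": {g: self.group_log_means[g].to_dict() for g in self.group_log_means},
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass(frozen=True)
class StudyData:
    counts: dict[int, CountTable]  # per experiment, raw counts
    host: HostTable  # all samples, natural scale
    metadata: SampleMetadata
    truth: GroundTruth


def _sample_ids(exp: int, group: str, n: int) -> list[str]:
    return [f"E{exp}.{group}.m{i + 1}" for i in range(n)]


def generate_study(cfg: SimulationConfig) -> StudyData:
    """Draw one full two-experiment study; bitwise reproducible per seed."""
    rng = np.random.default_rng(cfg.seed)
    k = cfg.nb_dispersion

    asv_ids = [f"ASV{i + 1}" for i in range(cfg.n_asvs)]
    membership = pd.Series("null", index=pd.Index(asv_ids, name="feature_id"), dtype=object)
    order = rng.permutation(cfg.n_asvs)
    pos = 0
    for cat, n_cat in (
        ("reversed", cfg.n_reversed),
        ("treatment_only", cfg.n_treatment_only),
        ("diet_only", cfg.n_diet_only),
    ):
        membership.iloc[order[pos : pos + n_cat]] = cat
        pos += n_cat

    base = rng.normal(cfg.baseline_log_mean, cfg.asv_log_sd, size=cfg.n_asvs)
    # Shift directions balanced within each planted category — alternating
    # down the abundance ranking, so that the heaviest shifted taxa roughly
    # cancel and group totals (hence relative abundances of unshifted taxa)
    # stay comparable between groups.
    sign = rng.choice([-1.0, 1.0], size=cfg.n_asvs)
    for cat in ("reversed", "treatment_only", "diet_only"):
        members = np.flatnonzero((membership == cat).to_numpy())
        by_abundance = members[np.argsort(-base[members])]
        start = rng.choice([-1.0, 1.0])
        sign[by_abundance] = start * np.tile([1.0, -1.0], len(members) // 2 + 1)[: len(members)]

    # group-dependent log-means: ln mu[i, g]
    delta = pd.DataFrame(0.0, index=asv_ids, columns=list(GROUPS))
    eff = cfg.effect_log_fold
    is_rev = (membership == "reversed").to_numpy()
    is_trt = (membership == "treatment_only").to_numpy()
    is_diet = (membership == "diet_only").to_numpy()
    delta.loc[is_rev, Group.WD.value] = sign[is_rev] * eff
    delta.loc[is_trt, Group.WD_Ch.value] = sign[is_trt] * eff
    delta.loc[is_diet, Group.WD.value] = sign[is_diet] * eff
    delta.loc[is_diet, Group.WD_Ch.value] = sign[is_diet] * eff
    group_log_means = delta.add(base, axis=0)

    reversed_ids = list(membership.index[membership == "reversed"])
    bridge_asv = reversed_ids[rng.integers(len(reversed_ids))] if reversed_ids else asv_ids[0]
    bridge_idx = asv_ids.index(bridge_asv)
    s_bridge = sign[bridge_idx]

    # log-scale latent sd matching the NB's Gamma mixing noise: sd(ln Gamma(k)) = sqrt(psi'(k))
    lat_sd = math.sqrt(float(polygamma(1, k)))
    rho_m = cfg.module_coupling

    # Treatment-responsive ASVs co-vary along one community axis centred on the
    # bridge (the treatment reshapes the community coherently, as co-responding
    # guilds do in real data). Coupled ASVs draw a lognormal latent with the NB's
    # log-scale variance, re-allocating a share rho_m of it to the bridge axis,
    # so coupling leaves each ASV's marginal mean and variance unchanged.
    # Coupling signs follow the fold-change sign rule the causality filter tests.
    coupled_idx: list[int] = []
    coupled_csign: list[float] = []
    for i, fid in enumerate(asv_ids):
        cat = membership.iloc[i]
        if fid == bridge_asv or rho_m <= 0:
            continue
        if cat == "reversed":
            coupled_idx.append(i)
            coupled_csign.append(sign[i] * s_bridge)
    coupled_arr = np.array(coupled_idx, dtype=int)
    csign_arr = np.array(coupled_csign)

    pheno_ids = [f"pheno{i + 1}" for i in range(cfg.n_phenotypes)]
    gene_ids = [f"gene{i + 1}" for i in range(cfg.n_genes)]
    host_ids = pheno_ids + gene_ids
    bridge_phen, bridge_gene = pheno_ids[0], gene_ids[0]

    # Host parameters share one latent "metabolic state" factor F (metabolic
    # readouts co-vary in real animals); in the treated group F is partly
    # driven by the bridge ASV's latent, which is the planted transkingdom
    # bridge. Loadings are signed by each parameter's response direction so
    # genuine correlations agree with the causality filter's sign rule.
    rho = cfg.bridge_strength
    # Target loadings compensate rank attenuation between observed counts and
    # the latent log-abundance (sequencing depth, Poisson noise, finite-sample
    # bias), so the measured bridge-target Spearman lands near bridge_strength.
    alpha_t = min(1.0, 1.16 * rho)  # target loading on the bridge axis
    beta_t = min(0.36, math.sqrt(max(0.0, 1.0 - alpha_t**2)))  # target loading on G
    b_cluster = 0.625 * rho  # bridge-axis share of the cluster hosts' couplings
    w_other = math.sqrt(cfg.host_factor_weight)

    host_sign = rng.choice([-1.0, 1.0], size=len(host_ids))
    host_mu = pd.DataFrame(0.0, index=host_ids, columns=list(GROUPS))
    load_axis = np.zeros(len(host_ids))  # signed loading on the bridge axis zeta
    load_g = np.zeros(len(host_ids))  # signed loading on the metabolic factor G
    for i, pid in enumerate(host_ids):
        if pid == bridge_phen:
            u = s_bridge
        elif pid == bridge_gene:
            u = -s_bridge
        else:
            u = host_sign[i]
        if pid in pheno_ids:
            # diet-induced, restored by treatment: fold-change sign is -u
            host_mu.at[pid, Group.WD.value] = u * cfg.host_effect
            fc = -u
        else:
            # treatment-only response: fold-change sign is +u
            host_mu.at[pid, Group.WD_Ch.value] = u * cfg.host_effect
            fc = u
        if pid in (bridge_phen, bridge_gene):
            load_axis[i] = fc * alpha_t
            load_g[i] = fc * beta_t
        else:
            load_axis[i] = fc * w_other * b_cluster
            load_g[i] = fc * w_other * math.sqrt(1.0 - b_cluster**2)
    load_eps = np.sqrt(np.clip(1.0 - load_axis**2 - load_g**2, 0.0, None))

    meta_rows: list[tuple[str, int, str]] = []
    counts: dict[int, CountTable] = {}
    host_cols: dict[str, np.ndarray] = {}

    for exp in range(1, cfg.n_experiments + 1):
        exp_samples: list[str] = []
        mat_cols: list[np.ndarray] = []
        for group in GROUPS:
            sids = _sample_ids(exp, group, cfg.n_mice_per_group)
            n = len(sids)
            exp_samples.extend(sids)
            meta_rows.extend((s, exp, group) for s in sids)

            mu = np.exp(group_log_means[group].to_numpy())  # per-ASV NB mean
            depth = np.exp(rng.normal(0.0, cfg.depth_log_sd, size=n))
            lam = rng.gamma(k, 1.0, size=(cfg.n_asvs, n)) * (mu[:, None] / k)

            # bridge + coupled module: lognormal latent with NB-matched moments
            z = rng.normal(0.0, 1.0, size=n)  # standardized bridge latent
            lam[bridge_idx] = np.exp(np.log(mu[bridge_idx]) - lat_sd**2 / 2.0 + lat_sd * z)
            if len(coupled_arr):
                c = rho_m if group == Group.WD_Ch.value else 0.0
                eps = rng.normal(0.0, 1.0, size=(len(coupled_arr), n))
                mix = c * csign_arr[:, None] * z[None, :] + math.sqrt(1.0 - c**2) * eps
                lam[coupled_arr] = np.exp(
                    np.log(mu[coupled_arr])[:, None] - lat_sd**2 / 2.0 + lat_sd * mix
                )

            cnt = rng.poisson(lam * depth[None, :]).astype(float)
            mat_cols.append(cnt)

            # host parameters, natural scale; the bridge axis carries the
            # planted transkingdom link only in the treated group
            eps = rng.normal(0.0, 1.0, size=(len(host_ids), n))
            g_factor = rng.normal(0.0, 1.0, size=n)
            zz = z if group == Group.WD_Ch.value else rng.normal(0.0, 1.0, size=n)
            zeta = -s_bridge * zz  # treatment-response axis, oriented by fold change
            latent = (
                load_axis[:, None] * zeta[None, :]
                + load_g[:, None] * g_factor[None, :]
                + load_eps[:, None] * eps
            )
            hmat = np.exp(host_mu[group].to_numpy()[:, None] + cfg.host_noise_sd * latent)
            for j, s in enumerate(sids):
                host_cols[s] = hmat[:, j]

        mat = np.concatenate(mat_cols, axis=1)
        counts[exp] = CountTable(
            pd.DataFrame(mat, index=asv_ids, columns=exp_samples), scale=Scale.raw_counts
        )

    meta = SampleMetadata(
        pd.DataFrame(
            {"experiment": [r[1] for r in meta_rows], "group": [r[2] for r in meta_rows]},
            index=pd.Index([r[0] for r in meta_rows], name="sample_id"),
        )
    )
    host_data = pd.DataFrame(host_cols, index=host_ids)[meta.sample_ids]
    host_info = pd.DataFrame(
        {
            "kind": ["phenotype"] * len(pheno_ids) + ["gene"] * len(gene_ids),
            "tissue": [""] * len(pheno_ids) + ["ileum" if i % 2 == 0 else "liver" for i in range(len(gene_ids))],
        },
        index=pd.Index(host_ids, name="parameter_id"),
    )
    host = HostTable(host_data, host_info)

    truth = GroundTruth(
        membership=membership,
        bridge_asv_id=bridge_asv,
        bridge_gene_id=bridge_gene,
        bridge_phenotype_id=bridge_phen,
        group_log_means=group_log_means,
    )
    return StudyData(counts=counts, host=host, metadata=meta, truth=truth)


def truth_report(truth: GroundTruth, called: Mapping[str, str]) -> pd.DataFrame:
    """Confusion summary of predicted response-group labels against the
    planted membership.

    ``called`` maps feature_id -> predicted category (features absent from
    the mapping count as predicted ``null``). Returns one row per planted
    category with true/false positive counts, sensitivity and empirical FDR.
    """
    universe = set(truth.membership.index)
    extra = set(called) - universe
    if extra:
        raise ValueError(f"called features outside the simulated universe: {sorted(extra)[:5]}")
    rows = []
    for cat in ("reversed", "treatment_only", "diet_only"):
        truth_set = set(truth.features(cat))
        called_set = {f for f, lab in called.items() if lab == cat}
        tp = len(truth_set & called_set)
        fp = len(called_set - truth_set)
        fn = len(truth_set - called_set)
        rows.append(
            {
                "category": cat,
                "n_true": len(truth_set),
                "n_called": len(called_set),
                "tp": tp,
                "fp": fp,
                "fn": fn,
                "sensitivity": tp / len(truth_set) if truth_set else float("nan"),
                "fdr": fp / len(called_set) if called_set else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("category")
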