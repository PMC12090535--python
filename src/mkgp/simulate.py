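"""Synthetic inbred diversity panel: genotypes, transcriptome, phenotypes.

Emulates the data structure of a multi-environment wheat trial so the
whole prediction pipeline is testable without the real panel:

* ~300 largely inbred lines genotyped at thousands of biallelic SNPs
  (independent markers, allele frequencies uniform over a configurable MAF
  window, heterozygosity depressed by the inbreeding coefficient f);
* thousands of transcript abundances per line *per environment*, each gene
  a sparse linear read-out of marker dosages plus an environment main
  effect, a genotype-by-environment component and Gaussian noise — the
  mechanism by which expression sits between genome and phenotype;
* phenotypes generated from the same kernel machinery the models assume:
  each random effect drawn from N(0, sigma^2 K), expanded to observations
  through incidence matrices, plus iid noise.

Randomness: a single `numpy.random.default_rng` seeded from
``SimConfig.seed`` via ``SeedSequence.spawn`` — one child stream per stage
(genotypes, transcriptome, each trait) so regenerating one stage never
shifts another.  Identical configs give bitwise-identical panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import warn
from .kernels import (
    GenotypePanel,
    IncidenceMatrix,
    KernelMatrix,
    epistasis_kernel,
    dominance_kernel,
    grm_linear,
    gxe_block_kernel,
    incidence_matrix,
)

__all__ = ["SimConfig", "SimPanel", "simulate_genotypes", "simulate_transcriptome",
           "simulate_phenotypes", "simulate_study"]


@dataclass
class SimConfig:
    """Generative settings for one synthetic trait on one panel.

    Variance components are on the trait scale (units squared) and play the
    generative role of the model's genomic, epistatic, dominance, G x E and
    residual variances.  ``transcriptome_h2`` / ``transcriptome_env_frac``
    give the fraction of each transcript's variance driven by genotype and
    by environment (main + interaction, split evenly); the remainder is
    noise.
    """

    n_lines: int = 286
    n_markers: int = 3000
    n_genes: int = 2000
    n_envs: int = 2
    reps_per_env: int = 1
    inbreeding_f: float = 0.95
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_subpops: int = 20
    fst: float = 0.35
    var_additive: float = 1.0
    var_epistatic: float = 0.0
    var_dominance: float = 0.0
    var_gxe: float = 0.0
    gxe_env_corr: float = 0.0
    var_residual: float = 1.0
    transcriptome_h2: float = 0.4
    transcriptome_env_frac: float = 0.3
    intercept: float = 100.0
    env_offsets: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0 <= self.inbreeding_f <= 1:
            raise ValueError("inbreeding_f must lie in [0, 1]")
        for name in ("var_additive", "var_epistatic", "var_dominance", "var_gxe", "var_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_envs < 1:
            raise ValueError("n_envs must be >= 1")
        if self.transcriptome_h2 < 0 or self.transcriptome_env_frac < 0:
            raise ValueError("transcriptome variance fractions must be >= 0")
        if self.transcriptome_h2 + self.transcriptome_env_frac > 1:
            raise ValueError("transcriptome_h2 + transcriptome_env_frac must not exceed 1")
        if self.n_envs > 1 and not (-1.0 / (self.n_envs - 1) <= self.gxe_env_corr <= 1.0):
            raise ValueError("gxe_env_corr outside the PSD range [-1/(n_envs-1), 1]")
        if self.n_subpops < 1:
            raise ValueError("n_subpops must be >= 1")
        if not 0 <= self.fst < 1:
            raise ValueError("fst must lie in [0, 1)")

    @property
    def env_labels(self) -> list[str]:
        return [f"env{j + 1}" for j in range(self.n_envs)]

    def rng_for(self, stage: str) -> np.random.Generator:
        """Per-stage child stream: deterministic, independent across stages."""
        import zlib

        stages = ("genotypes", "transcriptome", "phenotypes")
        if stage in stages:
            k = stages.index(stage)
        else:
            k = 3 + (zlib.crc32(stage.encode()) % 997)
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(k,))
        )


@dataclass
class SimPanel:
    """A generated data set plus the ground truth used to generate it."""

    genotypes: GenotypePanel
    abundances: pd.DataFrame  # MultiIndex (line, env) x genes
    phenotypes: pd.DataFrame  # columns: line, env, <trait columns>
    true_effects: dict  # trait -> {term -> obs-level vector}, variances, intercepts
    config: SimConfig


def simulate_genotypes(cfg: SimConfig) -> GenotypePanel:
    """Draw biallelic dosages for a structured, largely inbred panel.

    Per marker, the panel-level allele frequency is p ~ U(maf_range).  A
    diversity panel is not a random-mating population: lines fall into
    ``n_subpops`` families/subpopulations whose frequencies drift around p
    under the Balding–Nichols model, p_s ~ Beta(p(1-c)/c, (1-p)(1-c)/c)
    with differentiation c = ``fst``, creating the kinship between related
    lines that genomic prediction exploits.  Within a subpopulation,
    genotype frequencies are the inbreeding-adjusted Hardy–Weinberg
    proportions: the heterozygote class is scaled by (1 - f) with the
    deficit returned to the homozygotes, so the realised GRM diagonal
    averages 1 + f (plus a Wahlund inflation when fst > 0).  With
    ``n_subpops=1`` the panel is an unstructured Hardy–Weinberg draw.
    Monomorphic columns are resampled.
    """
    rng = cfg.rng_for("genotypes")
    f = cfg.inbreeding_f
    if f == 1.0:
        warn(
            "DOMINANCE_INESTIMABLE",
            "inbreeding_f=1: no heterozygotes will be generated, so the "
            "dominance design is constant and its variance is inestimable",
        )
    l, m = cfg.n_lines, cfg.n_markers
    n_sub = min(cfg.n_subpops, l)
    fam = np.repeat(np.arange(n_sub), -(-l // n_sub))[:l]
    codes = np.empty((l, m), dtype=float)
    todo = np.arange(m)
    for _ in range(200):
        mt = len(todo)
        p = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=mt)
        if n_sub > 1 and cfg.fst > 0:
            c = cfg.fst
            ps = rng.beta(
                p * (1 - c) / c, (1 - p) * (1 - c) / c, size=(n_sub, mt)
            )
        else:
            ps = np.broadcast_to(p, (n_sub, mt))
        pline = ps[fam]  # per-line subpopulation frequencies
        p_het = 2 * pline * (1 - pline) * (1 - f)
        p_hom_alt = pline * pline + pline * (1 - pline) * f
        u = rng.random((l, mt))
        g = np.where(u < p_hom_alt, 2.0, np.where(u < p_hom_alt + p_het, 1.0, 0.0))
        codes[:, todo] = g
        mono = g.min(axis=0) == g.max(axis=0)
        if not mono.any():
            break
        todo = todo[mono]
    else:
        raise RuntimeError("could not generate polymorphic markers; widen maf_range")
    line_ids = np.array([f"line{i + 1:04d}" for i in range(l)], dtype=object)
    return GenotypePanel(line_ids=line_ids, codes=codes)


def simulate_transcriptome(panel: GenotypePanel, cfg: SimConfig) -> pd.DataFrame:
    """Per-environment transcript abundances on a normalised continuous scale.

    Gene g in environment j for line i:

        a_ijg = b_g' x_i            (genetic, variance transcriptome_h2)
              + m_jg                (environment main, env_frac / 2)
              + c_jg' x_i           (G x E, env_frac / 2)
              + noise               (remainder)

    where b_g and c_jg load on a small random subset of centred marker
    dosages, rescaled so the realised variance shares match the config.
    Returned as a (line, env)-indexed frame so the transcriptome kernel can
    be built at observation level.
    """
    rng = cfg.rng_for("transcriptome")
    X = panel.codes - panel.codes.mean(axis=0)
    l, m = X.shape
    n_genes, n_envs = cfg.n_genes, cfg.n_envs
    h2, envf = cfg.transcriptome_h2, cfg.transcriptome_env_frac
    noise_var = 1.0 - h2 - envf
    k = min(10, m)

    rows = []
    genetic = np.zeros((l, n_genes))
    for g in range(n_genes):
        idx = rng.choice(m, size=k, replace=False)
        b = rng.standard_normal(k)
        score = X[:, idx] @ b
        genetic[:, g] = _scale_to_var(score, h2)
    env_main = rng.standard_normal((n_envs, n_genes)) * np.sqrt(envf / 2.0 if n_envs > 1 else 0.0)
    frames = []
    for j in range(n_envs):
        gxe = np.zeros((l, n_genes))
        if n_envs > 1 and envf > 0:
            for g in range(n_genes):
                idx = rng.choice(m, size=k, replace=False)
                c = rng.standard_normal(k)
                gxe[:, g] = _scale_to_var(X[:, idx] @ c, envf / 2.0)
        noise = rng.standard_normal((l, n_genes)) * np.sqrt(max(noise_var, 0.0))
        ab = genetic + env_main[j] + gxe + noise
        frames.append(
            pd.DataFrame(
                ab,
                index=pd.MultiIndex.from_arrays(
                    [panel.line_ids, [cfg.env_labels[j]] * l], names=("line", "env")
                ),
                columns=[f"gene{g + 1:05d}" for g in range(n_genes)],
            )
        )
    return pd.concat(frames)


def _scale_to_var(x: np.ndarray, target: float) -> np.ndarray:
    s = x.std()
    if s == 0 or target == 0:
        return np.zeros_like(x)
    return x * np.sqrt(target) / s


def _draw_effect(rng: np.random.Generator, K: np.ndarray, variance: float) -> np.ndarray:
    """Sample N(0, variance * K) via the eigendecomposition of K."""
    w, U = np.linalg.eigh(0.5 * (K + K.T))
    lam_max = max(w[-1], 0.0)
    if w[0] < -1e-8 * max(lam_max, 1e-300):
        raise ValueError("effect kernel is not PSD")
    w = np.clip(w, 0.0, None)
    return (U * np.sqrt(variance * w)) @ rng.standard_normal(len(w))


def simulate_phenotypes(
    panel: GenotypePanel,
    kernels: Mapping[str, KernelMatrix],
    cfg: SimConfig,
    trait: str = "trait",
    rng: np.random.Generator | None = None,
) -> SimPanel:
    """Generate one trait from line-level kernels plus iid noise.

    ``kernels`` maps term names to line-level kernels; variances come from
    the config by kernel kind (G -> var_additive, EPI -> var_epistatic,
    A -> var_dominance, GxE handled internally from the G kernel).  Effects
    are expanded to observations (n_envs x reps_per_env per line) through
    incidence matrices, exactly mirroring the fitted model's structure.
    """
    rng = rng or cfg.rng_for("phenotypes")
    var_of_kind = {"G": cfg.var_additive, "EPI": cfg.var_epistatic, "A": cfg.var_dominance}

    lines = panel.line_ids
    obs = []
    for j, env in enumerate(cfg.env_labels):
        for rep in range(cfg.reps_per_env):
            for li in lines:
                obs.append((li, env, rep))
    obs_ids = np.array([f"{li}@{env}#{rep}" for li, env, rep in obs], dtype=object)
    line_of = {o: li for o, (li, env, rep) in zip(obs_ids, obs)}
    env_of = {o: env for o, (li, env, rep) in zip(obs_ids, obs)}
    Zg = incidence_matrix(obs_ids, line_of, list(lines))
    Ze = incidence_matrix(obs_ids, env_of, cfg.env_labels)

    n = len(obs_ids)
    y = np.full(n, cfg.intercept)
    offsets = cfg.env_offsets or tuple(0.0 for _ in range(cfg.n_envs))
    if len(offsets) != cfg.n_envs:
        raise ValueError("env_offsets length must equal n_envs")
    y += Ze.entries @ np.asarray(offsets, dtype=float)

    effects: dict[str, np.ndarray] = {}
    for name, K in kernels.items():
        if K.kind == "GxE":
            continue  # handled below at observation level
        variance = var_of_kind.get(K.kind)
        if variance is None:
            raise ValueError(f"no generative variance configured for kernel kind {K.kind!r}")
        if variance == 0:
            continue
        if K.kind == "A" and (panel.codes == 1).sum() == 0:
            warn(
                "DOMINANCE_INESTIMABLE",
                "no heterozygotes in panel: dominance effect skipped",
            )
            continue
        g_line = _draw_effect(rng, K.entries, variance)
        effects[name] = Zg.entries @ g_line
        y += effects[name]

    if cfg.var_gxe > 0:
        if cfg.n_envs < 2:
            raise ValueError("var_gxe > 0 requires at least two environments")
        Gk = next((K for K in kernels.values() if K.kind == "G"), None)
        if Gk is None:
            Gk = grm_linear(panel)
        # per-environment genetic deviations with covariance
        # sigma^2 (Sigma_rho (x) G): rho=0 recovers the block kernel draw,
        # rho<0 gives crossover interaction (rankings flip across envs)
        rho = cfg.gxe_env_corr
        J = cfg.n_envs
        sigma_env = (1.0 - rho) * np.eye(J) + rho * np.ones((J, J))
        Le = np.linalg.cholesky(sigma_env + 1e-12 * np.eye(J))
        w, U = np.linalg.eigh(0.5 * (Gk.entries + Gk.entries.T))
        Lg = U * np.sqrt(np.clip(w, 0.0, None))
        ge_lines = np.sqrt(cfg.var_gxe) * (Lg @ rng.standard_normal((len(lines), J)) @ Le.T)
        effects["gxe"] = sum(
            Ze.entries[:, j] * (Zg.entries @ ge_lines[:, j]) for j in range(J)
        )
        y += effects["gxe"]

    noise = rng.standard_normal(n) * np.sqrt(cfg.var_residual)
    y = y + noise
    effects["residual"] = noise

    pheno = pd.DataFrame(
        {
            "line": [li for li, env, rep in obs],
            "env": [env for li, env, rep in obs],
            trait: y,
        }
    )
    truth = {
        trait: {
            "effects": effects,
            "variances": {
                "additive": cfg.var_additive,
                "epistatic": cfg.var_epistatic,
                "dominance": cfg.var_dominance,
                "gxe": cfg.var_gxe,
                "residual": cfg.var_residual,
            },
            "intercept": cfg.intercept,
            "env_offsets": tuple(offsets),
            "obs_ids": obs_ids,
        }
    }
    return SimPanel(
        genotypes=panel,
        abundances=pd.DataFrame(),
        phenotypes=pheno,
        true_effects=truth,
        config=cfg,
    )


#: default generative settings for the two study traits: flowering time is
#: strongly G x E-mediated, height mostly additive.
DEFAULT_TRAITS: dict[str, dict] = {
    "flowering": dict(
        var_additive=0.5, var_epistatic=0.1, var_gxe=1.5, var_residual=0.5,
        intercept=100.0, env_offsets_scale=8.0,
    ),
    "height": dict(
        var_additive=1.5, var_epistatic=0.1, var_gxe=0.1, var_residual=0.5,
        intercept=90.0, env_offsets_scale=2.0,
    ),
}


def simulate_study(
    cfg: SimConfig, traits: Mapping[str, Mapping] | None = None
) -> SimPanel:
    """Generate the full two-trait study panel: genotypes, per-environment
    transcriptome, and phenotypes for each trait.

    ``traits`` maps trait name -> overrides of the variance fields of
    ``cfg`` (plus optional ``env_offsets_scale`` spreading environment
    means); defaults to a G x E-dominated flowering trait and a mostly
    additive height trait.
    """
    traits = traits if traits is not None else DEFAULT_TRAITS
    panel = simulate_genotypes(cfg)
    abundances = simulate_transcriptome(panel, cfg)
    G = grm_linear(panel)
    kernels = {"g": G, "epi": epistasis_kernel(G)}

    pheno = None
    truth: dict = {}
    for t, (name, overrides) in enumerate(traits.items()):
        overrides = dict(overrides)
        scale = overrides.pop("env_offsets_scale", 0.0)
        offsets = tuple(scale * j for j in range(cfg.n_envs))
        tcfg = replace(cfg, env_offsets=offsets, **overrides)
        sp = simulate_phenotypes(
            panel, kernels, tcfg, trait=name, rng=cfg.rng_for(f"trait:{name}")
        )
        truth.update(sp.true_effects)
        if pheno is None:
            pheno = sp.phenotypes
        else:
            pheno[name] = sp.phenotypes[name]
    return SimPanel(
        genotypes=panel,
        abundances=abundances,
        phenotypes=pheno,
        true_effects=truth,
        config=cfg,
    )
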