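"""The 13 published model scenarios, assembled from a data bundle.

GBLUP scenarios combine the linear additive GRM (G) with explicit
epistatic (G#G, ``EPI``), dominance (``A``), transcriptome (``T``) and
genotype-by-environment (``G x E``) terms; RKHS scenarios replace the
separate genomic terms with a single Gaussian kernel G* that captures
additive plus cryptic non-additive effects jointly.

Scenario ids and their term lists::

    G              g
    G_EPI          g + g_ep
    G_EPI_A        g + g_ep + g_a
    G_GE           g + gE
    G_GE_EPI       g + gE + g_ep
    G_T            g + t
    G_T_EPI        g + t + g_ep
    G_T_GE_EPI     g + t + gE + g_ep
    G_T_GE_EPI_A   g + t + gE + g_ep + g_a
    RKHS_G         g*
    RKHS_T         t
    RKHS_G_T       g* + t
    RKHS_G_T_GE    g* + t + g*E

Every model also carries per-environment intercepts mu_j whenever the
bundle declares more than one environment, and an iid residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import warn
from .evaluation import CVReport, FoldPlan, crossvalidate, make_folds
from .inference import ChainConfig, ModelSpec, RandomEffectTerm
from .kernels import (
    GenotypePanel,
    IncidenceMatrix,
    KernelMatrix,
    center_genotypes,
    dominance_kernel,
    epistasis_kernel,
    gaussian_kernel,
    grm_linear,
    gxe_block_kernel,
    incidence_matrix,
    median_bandwidth,
    transcriptome_kernel,
)

__all__ = ["SCENARIO_IDS", "DataBundle", "build_scenario", "run_catalog", "scenario_terms"]

SCENARIO_IDS = (
    "G",
    "G_EPI",
    "G_EPI_A",
    "G_GE",
    "G_GE_EPI",
    "G_T",
    "G_T_EPI",
    "G_T_GE_EPI",
    "G_T_GE_EPI_A",
    "RKHS_G",
    "RKHS_T",
    "RKHS_G_T",
    "RKHS_G_T_GE",
)

#: term composition of each scenario (order matters for reporting)
_SCENARIO_TERMS: dict[str, tuple[str, ...]] = {
    "G": ("g",),
    "G_EPI": ("g", "g_ep"),
    "G_EPI_A": ("g", "g_ep", "g_a"),
    "G_GE": ("g", "gxe"),
    "G_GE_EPI": ("g", "gxe", "g_ep"),
    "G_T": ("g", "t"),
    "G_T_EPI": ("g", "t", "g_ep"),
    "G_T_GE_EPI": ("g", "t", "gxe", "g_ep"),
    "G_T_GE_EPI_A": ("g", "t", "gxe", "g_ep", "g_a"),
    "RKHS_G": ("g_star",),
    "RKHS_T": ("t",),
    "RKHS_G_T": ("g_star", "t"),
    "RKHS_G_T_GE": ("g_star", "t", "gxe_star"),
}


def scenario_terms(scenario_id: str) -> tuple[str, ...]:
    """Term names composing a scenario (table-driven contract)."""
    _check_id(scenario_id)
    return _SCENARIO_TERMS[scenario_id]


def _check_id(scenario_id: str) -> None:
    if scenario_id not in _SCENARIO_TERMS:
        raise KeyError(
            f"unknown scenario {scenario_id!r}; valid ids: {', '.join(SCENARIO_IDS)}"
        )


@dataclass
class DataBundle:
    """Everything the scenario builders need, aligned on line ids.

    ``phenotypes`` holds one row per observation (columns ``line``, ``env``
    plus trait columns).  ``abundances`` may be indexed per (line, env) —
    the transcriptome kernel is then built at observation level, letting it
    absorb environmental signal — or per line only.
    """

    genotypes: GenotypePanel
    phenotypes: pd.DataFrame
    abundances: pd.DataFrame | None = None
    bandwidth: float | None = None
    gaussian_scale_by_features: bool = False

    def __post_init__(self):
        for col in ("line", "env"):
            if col not in self.phenotypes.columns:
                raise ValueError(f"phenotype table lacks required column {col!r}")
        known = set(self.genotypes.line_ids)
        unknown = set(self.phenotypes["line"]) - known
        if unknown:
            raise ValueError(f"phenotype lines absent from genotypes: {sorted(unknown)[:5]}")
        self._cache: dict = {}

    # -- observation bookkeeping -------------------------------------------
    @property
    def environments(self) -> list:
        return list(dict.fromkeys(self.phenotypes["env"]))

    @property
    def obs_ids(self) -> np.ndarray:
        return np.asarray(
            [f"{l}@{e}#{i}" for i, (l, e) in enumerate(zip(self.phenotypes["line"], self.phenotypes["env"]))],
            dtype=object,
        )

    @property
    def trait_names(self) -> list:
        return [c for c in self.phenotypes.columns if c not in ("line", "env")]

    def _cached(self, key, fn):
        if key not in self._cache:
            self._cache[key] = fn()
        return self._cache[key]

    def incidence_lines(self) -> IncidenceMatrix:
        return self._cached(
            "Zg",
            lambda: incidence_matrix(
                self.obs_ids,
                dict(zip(self.obs_ids, self.phenotypes["line"])),
                list(self.genotypes.line_ids),
            ),
        )

    def incidence_envs(self) -> IncidenceMatrix:
        return self._cached(
            "Ze",
            lambda: incidence_matrix(
                self.obs_ids,
                dict(zip(self.obs_ids, self.phenotypes["env"])),
                self.environments,
            ),
        )

    # -- kernels ------------------------------------------------------------
    def grm(self) -> KernelMatrix:
        return self._cached("G", lambda: grm_linear(self.genotypes))

    def epistasis(self) -> KernelMatrix:
        return self._cached("EPI", lambda: epistasis_kernel(self.grm()))

    def dominance(self) -> KernelMatrix:
        return self._cached("A", lambda: dominance_kernel(self.genotypes))

    def gaussian(self) -> KernelMatrix:
        def build():
            W, _ = center_genotypes(self.genotypes)
            h = self.bandwidth
            if h is None:
                h = median_bandwidth(W, self.gaussian_scale_by_features)
                warn("BANDWIDTH_DEFAULT", f"Gaussian bandwidth set by median heuristic: h={h:.4g}")
            return gaussian_kernel(
                W, h, self.genotypes.line_ids, self.gaussian_scale_by_features
            )

        return self._cached("GAUSS", build)

    def transcriptome(self) -> tuple[KernelMatrix, IncidenceMatrix | None]:
        """Transcriptome kernel plus the incidence mapping (None = obs level)."""
        if self.abundances is None:
            raise ValueError("scenario requires transcript abundances, none in bundle")

        def build():
            ab = self.abundances
            if isinstance(ab.index, pd.MultiIndex):
                # per (line, env) profiles: align rows to observations
                key = list(zip(self.phenotypes["line"], self.phenotypes["env"]))
                mat = ab.loc[key].to_numpy(dtype=float)
                return transcriptome_kernel(mat, self.obs_ids), None
            mat = ab.loc[list(self.genotypes.line_ids)].to_numpy(dtype=float)
            return transcriptome_kernel(mat, self.genotypes.line_ids), "lines"

        K, inc = self._cached("T", build)
        return K, (self.incidence_lines() if inc == "lines" else None)

    def gxe(self, base: KernelMatrix) -> KernelMatrix:
        if len(self.environments) < 2:
            raise ValueError("G x E scenario requires at least two environments")
        return self._cached(
            ("GxE", base.kind),
            lambda: gxe_block_kernel(base, self.incidence_lines(), self.incidence_envs()),
        )


def build_scenario(
    scenario_id: str, bundle: DataBundle, drop_dominance_if_inbred: bool = False
) -> ModelSpec:
    """Assemble the ModelSpec for one scenario from a data bundle.

    ``drop_dominance_if_inbred`` replaces the hard error on fully inbred
    panels (no heterozygotes anywhere) by a warning that silently drops the
    dominance term — used by :func:`run_catalog` so one degenerate term does
    not abort the whole catalog.
    """
    _check_id(scenario_id)
    Zg = bundle.incidence_lines()
    terms: list[RandomEffectTerm] = []
    for name in _SCENARIO_TERMS[scenario_id]:
        if name == "g":
            terms.append(RandomEffectTerm("g", bundle.grm(), Zg))
        elif name == "g_ep":
            terms.append(RandomEffectTerm("g_ep", bundle.epistasis(), Zg))
        elif name == "g_a":
            try:
                terms.append(RandomEffectTerm("g_a", bundle.dominance(), Zg))
            except ValueError:
                if not drop_dominance_if_inbred:
                    raise
                warn("DOMINANCE_DROPPED", f"{scenario_id}: dominance term dropped (no heterozygotes)")
        elif name == "t":
            K, inc = bundle.transcriptome()
            terms.append(RandomEffectTerm("t", K, inc))
        elif name == "gxe":
            terms.append(RandomEffectTerm("gxe", bundle.gxe(bundle.grm()), None, genetic=False))
        elif name == "g_star":
            terms.append(RandomEffectTerm("g_star", bundle.gaussian(), Zg))
        elif name == "gxe_star":
            terms.append(
                RandomEffectTerm("gxe_star", bundle.gxe(bundle.gaussian()), None, genetic=False)
            )
        else:  # pragma: no cover
            raise AssertionError(name)
    environments = (
        bundle.phenotypes["env"].to_numpy() if len(bundle.environments) > 1 else None
    )
    return ModelSpec(terms=terms, environments=environments, obs_ids=bundle.obs_ids)


def run_catalog(
    bundle: DataBundle,
    traits: Sequence[str] | None = None,
    scenarios: Sequence[str] | str = "all",
    plan: FoldPlan | None = None,
    chain: ChainConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[tuple[str, str], CVReport]]:
    """Cross-validate scenarios x traits; returns a tidy accuracy table.

    Per-scenario failures (e.g. a G x E scenario on a single-environment
    bundle) are logged and skipped without aborting the remaining runs.
    """
    if scenarios == "all":
        scenarios = SCENARIO_IDS
    for sid in scenarios:
        _check_id(sid)
    traits = list(traits) if traits is not None else bundle.trait_names
    plan = plan or make_folds(bundle.genotypes.line_ids, seed)
    chain = chain or ChainConfig()

    rows = []
    reports: dict[tuple[str, str], CVReport] = {}
    for sid in scenarios:
        try:
            model = build_scenario(sid, bundle, drop_dominance_if_inbred=True)
        except Exception as exc:  # noqa: BLE001 - propagate as report row
            warn("SCENARIO_SKIPPED", f"{sid}: {exc}")
            for trait in traits:
                rows.append({"scenario": sid, "trait": trait, "mean_r": np.nan,
                             "std_r": np.nan, "error": str(exc)})
            continue
        for trait in traits:
            report = crossvalidate(model, bundle.phenotypes, trait, plan, chain, scenario_id=sid)
            reports[(sid, trait)] = report
            rows.append(
                {
                    "scenario": sid,
                    "trait": trait,
                    "mean_r": report.mean_r,
                    "std_r": report.std_r,
                    "pooled_r": report.pooled_r,
                    "error": "",
                }
            )
    return pd.DataFrame(rows), reports
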