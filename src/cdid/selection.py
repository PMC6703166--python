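"""DIC-based forward selection of design columns for the change model.

The base model is always [intercept, cdiff] (the clinic-score change is the
exposure of interest and never dropped).  Single-addition DIC reductions rank
the candidates; candidates are then added cumulatively in that order, stopping
at the first addition that does not strictly reduce DIC.  Both the change and
baseline regressions share the selected column set; selection is driven by the
change model's DIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .data_model import DesignMatrix
from .priors import PriorConfig
from .sampler import ClinicData, compute_dic, run_gibbs

BASE_COLUMNS = ("intercept", "cdiff")


class SelectionError(RuntimeError):
    pass


@dataclass
class SelectionTrace:
    """Record of a forward-selection run.

    ``candidate_order`` is sorted by single-addition DIC reduction (descending,
    ties broken by candidate input order); ``step_dics`` holds the DIC after the
    base fit and after each accepted addition, so it is strictly decreasing.
    """

    base_columns: tuple[str, ...]
    candidate_order: list[str]
    single_addition_dic: dict[str, float]
    step_dics: list[float]
    selected: list[str]
    step_seeds: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "base_columns": list(self.base_columns),
            "candidate_order": self.candidate_order,
            "single_addition_dic": self.single_addition_dic,
            "step_dics": self.step_dics,
            "selected": self.selected,
            "step_seeds": self.step_seeds,
        }


def forward_select(data: ClinicData,
                   design_builder: Callable[[list[str]], DesignMatrix],
                   candidates: Sequence[str], *,
                   prior_config: PriorConfig | None = None,
                   n_iter: int = 20_000, burn_in: int = 2_000,
                   seed: int = 0, **gibbs_kwargs) -> SelectionTrace:
    """Forward-select design columns by DIC.

    ``design_builder`` maps an ordered column list (always starting with the
    base columns) to a :class:`DesignMatrix` — for registry data a closure over
    ``build_design_matrix(summaries, scores, ...)``, for synthetic data any
    constructor of the fitting design.  Candidates must be disjoint from the
    base columns.  A fixed per-step seed schedule derived from ``seed`` makes
    the trace reproducible.
    """
    candidates = list(candidates)
    overlap = set(candidates) & set(BASE_COLUMNS)
    if overlap:
        raise ValueError(f"candidates must be disjoint from base columns: {overlap}")

    n_fits = 1 + len(candidates) + len(candidates)  # base + screens + worst-case adds
    seeds = [int(s) for s in
             np.random.SeedSequence(seed).generate_state(n_fits, dtype=np.uint32)
             % np.uint32(2**31)]
    seed_iter = iter(seeds)
    used_seeds: list[int] = []

    def fit_dic(columns: list[str]) -> float:
        s = next(seed_iter)
        used_seeds.append(s)
        try:
            design = design_builder(columns)
            draws = run_gibbs(data, design, prior_config=prior_config,
                              n_iter=n_iter, burn_in=burn_in, seed=s,
                              compute_deviance=True, **gibbs_kwargs)
            return compute_dic(draws, data, design)
        except Exception as exc:  # noqa: BLE001 — named-column context matters
            raise SelectionError(
                f"fit failed for column set {columns}: {exc}") from exc

    base = list(BASE_COLUMNS)
    base_dic = fit_dic(base)

    reductions = []
    single = {}
    for k, cand in enumerate(candidates):
        dic_c = fit_dic(base + [cand])
        single[cand] = dic_c
        reductions.append((-(base_dic - dic_c), k, cand))  # sort key: reduction desc
    reductions.sort()
    order = [cand for _, _, cand in reductions]

    selected = list(base)
    step_dics = [base_dic]
    for cand in order:
        dic_new = fit_dic(selected + [cand])
        if dic_new < step_dics[-1]:
            selected.append(cand)
            step_dics.append(dic_new)
        else:
            break
    return SelectionTrace(base_columns=BASE_COLUMNS, candidate_order=order,
                          single_addition_dic=single, step_dics=step_dics,
                          selected=selected, step_seeds=used_seeds)
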