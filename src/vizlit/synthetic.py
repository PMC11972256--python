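"""Synthetic response cohorts with known latent structure.

The generator emulates the statistical structure the analysis pipeline
assumes so that every stage can be verified against ground truth:

* m binary items from an :class:`~vizlit.item_bank.AssessmentBank` (default:
  the 66-item combined fixture, 2 tests x 13 graph types x 11 question
  types);
* participants whose error probabilities follow a low-rank latent factor
  structure, mirroring the factor-model form X - mu = L F + eps;
* a math-coursework covariate (0-3 prior courses) positively associated
  with accuracy, and two sample groups with different mean ability;
* optional incompleteness, producing participants who fail the
  completeness exclusion.

Default cohort parameters follow the study design the pipeline targets:
1,113 retained participants in a roughly 36/64 representative/university
split, around 75% overall accuracy, a per-course log-odds effect of 0.2 on
correctness and a between-group log-odds gap of 0.25.

Two links map the linear structure to error probabilities: ``logistic``
(default; always yields valid probabilities and clean GLMM recovery) and
``linear_clipped`` (the factor model's linear form, clipped into [0, 1]).
The full generative record (loadings, scores, effects, cell probabilities)
is returned alongside the data so tests never re-derive ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special

from .item_bank import AssessmentBank, ItemSpec, combined_bank
from .scoring import ResponseRecord

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate_dataset", "truth_check"]

_MATH_COURSE_P = {
    # approximate study distribution of 0-3 prior math courses per group
    "representative": (0.10, 0.34, 0.29, 0.27),
    "university": (0.13, 0.07, 0.21, 0.59),
}


@dataclass
class SyntheticConfig:
    bank: AssessmentBank | None = None  # default: combined fixture
    n_participants: int = 1113
    f_true: int = 4
    loading_scheme: str = "random_sparse"  # | facet_indicator | user_supplied
    facet: str | None = None  # facet for facet_indicator
    loadings: np.ndarray | None = None  # for user_supplied
    loading_strength: float = 1.5
    ability_sd: float = 1.0
    item_difficulty_range: tuple[float, float] = (-2.5, 0.5)  # logit of error
    item_intercepts: np.ndarray | None = None  # overrides the sampled range
    math_effect: float = 0.2  # log-odds of correctness per course
    group_effect: float = 0.25  # university -> representative gain
    incomplete_rate: float = 0.05
    link: str = "logistic"  # | linear_clipped
    group_frac_representative: float = 399 / 1113
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        if self.f_true < 0:
            raise ValueError("f_true must be nonnegative")
        if not 0.0 <= self.incomplete_rate < 1.0:
            raise ValueError("incomplete_rate must be in [0, 1)")
        if self.link not in ("logistic", "linear_clipped"):
            raise ValueError(f"unknown link {self.link!r}")
        if self.loading_scheme not in (
            "random_sparse", "facet_indicator", "user_supplied"
        ):
            raise ValueError(f"unknown loading scheme {self.loading_scheme!r}")
        if self.loading_scheme == "facet_indicator" and self.facet is None:
            raise ValueError("facet_indicator scheme requires a facet")
        if self.loading_scheme == "user_supplied" and self.loadings is None:
            raise ValueError("user_supplied scheme requires loadings")
        lo, hi = self.item_difficulty_range
        if not lo <= hi:
            raise ValueError("empty item difficulty range")
        if self.link == "linear_clipped" and not (0.0 <= lo and hi <= 1.0):
            raise ValueError(
                "linear_clipped link needs item difficulties in [0, 1]"
            )


@dataclass
class SyntheticTruth:
    """Ground-truth generative record for a synthetic cohort."""

    L_true: np.ndarray
    F_true: np.ndarray
    item_intercepts: np.ndarray
    ability: np.ndarray
    math_courses: np.ndarray
    sample_group: np.ndarray
    math_effect: float
    group_effect: float
    f_true: int
    link: str
    seed: int
    p_error: np.ndarray
    X: np.ndarray  # complete error matrix before incompleteness injection
    participant_ids: list[str]
    item_ids: list[str]
    dataset_id: str = ""

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in asdict(self).items()
        }
        path.write_text(json.dumps(payload))
        return path


def _wrong_answer(item: ItemSpec) -> str:
    """A deterministic incorrect response for an item."""
    if item.response_format == "true_false":
        return "false" if item.answer_key.lower() == "true" else "true"
    if item.response_format in ("mc3", "mc4"):
        options = "abc" if item.response_format == "mc3" else "abcd"
        for opt in options:
            if opt != item.answer_key.lower():
                return opt
    try:
        return str(float(item.answer_key) + 7.0)
    except ValueError:
        return item.answer_key + "_x"


def _make_loadings(cfg: SyntheticConfig, bank: AssessmentBank, rng) -> np.ndarray:
    m = len(bank)
    if cfg.loading_scheme == "facet_indicator":
        from .factor_models import idealized_loading

        L = idealized_loading(bank, cfg.facet).L * cfg.loading_strength
    elif cfg.loading_scheme == "user_supplied":
        L = np.asarray(cfg.loadings, float)
        if L.shape[0] != m:
            raise ValueError("user loadings do not match bank size")
    else:  # random_sparse: each item loads on one random factor
        L = np.zeros((m, cfg.f_true))
        if cfg.f_true > 0:
            assign = rng.integers(0, cfg.f_true, size=m)
            # guarantee every factor is represented
            assign[: cfg.f_true] = np.arange(cfg.f_true)
            L[np.arange(m), assign] = cfg.loading_strength
    return L


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Sample a synthetic cohort.

    Returns ``(responses, demographics, truth)`` where ``responses`` is the
    long-format table the scoring module reads (participant_id, item_id,
    response), ``demographics`` has (participant_id, sample_group,
    math_courses), and ``truth`` records the full generative state.
    Deterministic given ``config.seed``.
    """
    config.validate()
    bank = config.bank if config.bank is not None else combined_bank()
    rng = np.random.default_rng(config.seed)
    m, n = len(bank), config.n_participants

    # participants: group, math coursework, general ability
    n_rep = int(round(config.group_frac_representative * n))
    groups = np.array(
        ["representative"] * n_rep + ["university"] * (n - n_rep)
    )
    courses = np.empty(n, dtype=int)
    for g, p in _MATH_COURSE_P.items():
        mask = groups == g
        courses[mask] = rng.choice(4, size=mask.sum(), p=p)
    ability = rng.normal(0.0, config.ability_sd, size=n)

    # latent structure
    L = _make_loadings(config, bank, rng)
    f = L.shape[1]
    F = rng.normal(size=(f, n))

    # per-cell error probability
    if config.item_intercepts is not None:
        d = np.asarray(config.item_intercepts, float)
        if d.shape != (m,):
            raise ValueError("item_intercepts must have one entry per item")
    else:
        d = rng.uniform(*config.item_difficulty_range, size=m)
    group_ind = (groups == "representative").astype(float)
    if config.link == "logistic":
        eta = (
            d[:, None]
            + L @ F
            - config.math_effect * courses[None, :]
            - config.group_effect * group_ind[None, :]
            - ability[None, :]
        )
        p_error = special.expit(eta)
    else:
        p_error = (
            d[:, None]
            + L @ F
            - config.math_effect * courses[None, :]
            - config.group_effect * group_ind[None, :]
            - ability[None, :]
        )
        p_error = np.clip(p_error, 0.0, 1.0)

    X = (rng.random((m, n)) < p_error).astype(float)

    pids = [f"p{j:05d}" for j in range(n)]
    demographics = pd.DataFrame(
        {"participant_id": pids, "sample_group": groups, "math_courses": courses}
    )

    # long-format responses; errors get a deterministic wrong answer
    wrongs = [_wrong_answer(it) for it in bank]
    keys = [it.answer_key for it in bank]
    records = {
        "participant_id": np.repeat(pids, m),
        "item_id": np.tile(bank.item_ids, n),
        "response": [
            wrongs[i] if X[i, j] else keys[i] for j in range(n) for i in range(m)
        ],
    }
    responses = pd.DataFrame(records)

    # inject incompleteness: drop one random item per affected participant
    n_inc = int(round(config.incomplete_rate * n))
    if n_inc:
        affected = rng.choice(n, size=n_inc, replace=False)
        drop_item = rng.integers(0, m, size=n_inc)
        drop_keys = {
            (pids[j], bank.item_ids[i]) for j, i in zip(affected, drop_item)
        }
        mask = [
            (p, i) not in drop_keys
            for p, i in zip(responses["participant_id"], responses["item_id"])
        ]
        responses = responses[mask].reset_index(drop=True)

    truth = SyntheticTruth(
        L_true=L,
        F_true=F,
        item_intercepts=d,
        ability=ability,
        math_courses=courses,
        sample_group=groups,
        math_effect=config.math_effect,
        group_effect=config.group_effect,
        f_true=f,
        link=config.link,
        seed=config.seed,
        p_error=p_error,
        X=X,
        participant_ids=pids,
        item_ids=list(bank.item_ids),
        dataset_id=f"synthetic-{config.seed}-{n}x{m}",
    )
    return responses, demographics, truth


# ---------------------------------------------------------------------------
# Recovery reporting.
# ---------------------------------------------------------------------------

def subspace_canonical_correlations(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Canonical correlations between the column spans of A and B."""
    Qa, _ = np.linalg.qr(np.asarray(A, float))
    Qb, _ = np.linalg.qr(np.asarray(B, float))
    s = np.linalg.svd(Qa.T @ Qb, compute_uv=False)
    return np.clip(s, 0.0, 1.0)


def truth_check(truth: SyntheticTruth, fits: dict) -> dict:
    """Compare pipeline outputs against the generative record.

    ``fits`` may contain ``selected_f`` (int), ``L_fit`` (m x f array) and
    ``math_effect_estimate`` with ``math_effect_se`` (per-course log-odds
    slope from a GLMM).  A ``dataset_id`` key, when present, must match the
    truth record.  Returns a recovery report dict.
    """
    if "dataset_id" in fits and fits["dataset_id"] != truth.dataset_id:
        raise ValueError("fits were not produced from this dataset")
    report: dict = {"dataset_id": truth.dataset_id}
    if "selected_f" in fits:
        report["f_true"] = truth.f_true
        report["f_selected"] = int(fits["selected_f"])
        report["factor_count_recovered"] = int(fits["selected_f"]) == truth.f_true
    if "L_fit" in fits and truth.f_true > 0:
        cc = subspace_canonical_correlations(truth.L_true, fits["L_fit"])
        report["loading_canonical_correlations"] = cc.tolist()
        report["min_canonical_correlation"] = float(cc.min())
    if "math_effect_estimate" in fits:
        est = float(fits["math_effect_estimate"])
        report["math_effect_true"] = truth.math_effect
        report["math_effect_estimate"] = est
        report["math_effect_bias"] = est - truth.math_effect
        if "math_effect_se" in fits:
            se = float(fits["math_effect_se"])
            report["math_effect_within_2se"] = abs(est - truth.math_effect) <= 2 * se
    return report
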