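"""Out-of-sample validation of hazard prediction.

Train CPTs by EM on one set of records; for each held-out case, enter the
observed input parameters as evidence, take the hazard state with the
highest posterior probability as the prediction, and compare it with the
hazard state observed in the literature. Ties go to the lowest-severity
state (deterministic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .em import learn_parameters_em, _MISSING_TOKENS
from .inference import infer_posterior
from .network import BNError, DiscreteBayesNet


def _observed(raw: object) -> bool:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return False
    return str(raw).strip().lower() not in _MISSING_TOKENS


@dataclass
class CrossValResult:
    accuracy: float
    accuracy_by_nm: dict[str, float]
    cases: pd.DataFrame  # per-case report: evidence, actual, predicted, correct
    n_flagged: int       # cases with no usable input evidence
    net: DiscreteBayesNet


def cross_validate(
    train: pd.DataFrame,
    test: pd.DataFrame,
    net: DiscreteBayesNet,
    hazard_node: str = "hazard",
    nm_node: str = "nanoparticle",
    max_iter: int = 200,
    tol: float = 1e-6,
    smoothing: float = 1.0,
    label_column: str | None = None,
) -> CrossValResult:
    """EM-train on ``train``, predict the hazard state of every ``test``
    case from its observed inputs, and report accuracy overall and per
    nanomaterial alongside a per-case table.

    ``label_column`` names the observed-hazard column when it differs from
    the hazard node (published case tables call it ``actual``).
    """
    label = label_column or hazard_node
    if label not in test.columns:
        raise BNError(f"test data has no {label!r} column")
    if label != hazard_node:
        train = train.rename(columns={label: hazard_node})
        test = test.rename(columns={label: hazard_node})
    # train/test disjointness is the caller's responsibility: distinct
    # studies can legitimately produce value-identical categorical records,
    # so row identity is not evidence of leakage

    fitted = learn_parameters_em(
        net, train, max_iter=max_iter, tol=tol, smoothing=smoothing
    ).net

    input_cols = [
        c for c in test.columns if c in fitted.nodes and c != hazard_node
    ]
    rows = []
    n_flagged = 0
    for _, case in test.iterrows():
        if not _observed(case[hazard_node]):
            continue
        evidence = {
            c: str(case[c]) for c in input_cols if _observed(case[c])
        }
        flagged = not evidence
        n_flagged += flagged
        post = infer_posterior(fitted, evidence, hazard_node)
        predicted = post.argmax_state
        actual = str(case[hazard_node])
        rows.append(
            {
                **{c: (str(case[c]) if _observed(case[c]) else "-") for c in input_cols},
                "actual": actual,
                "predicted": predicted,
                "correct": predicted == actual,
                "no_evidence": flagged,
            }
        )
    cases = pd.DataFrame(rows)
    if cases.empty:
        raise BNError("no test case carries an observed hazard label")
    accuracy = float(cases["correct"].mean())
    by_nm: dict[str, float] = {}
    if nm_node in cases.columns:
        for nm, grp in cases.groupby(nm_node):
            by_nm[str(nm)] = float(grp["correct"].mean())
    return CrossValResult(
        accuracy=accuracy,
        accuracy_by_nm=by_nm,
        cases=cases,
        n_flagged=n_flagged,
        net=fitted,
    )


def bn_testcases_fixture() -> pd.DataFrame:
    """The bundled 15-case out-of-sample harness table (input parameters,
    observed hazard, and the originally reported prediction), in the
    column layout consumed by :func:`cross_validate`."""
    ref = resources.files("nanohazard.data").joinpath("bn_test_cases.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, dtype=str, keep_default_na=False)
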