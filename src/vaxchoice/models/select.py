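"""Model selection by minimum BIC across fits on the same dataset."""

from __future__ import annotations

import pandas as pd


def model_selection(results: list, labels: list[str] | None = None) -> pd.DataFrame:
    """Rank fitted models by BIC (ascending); the minimum is selected.

    All results must have been fitted on the same number of choice
    observations, otherwise BICs are not comparable and a ValueError is
    raised.
    """
    if not results:
        raise ValueError("no results to rank")
    n_choices = {r.n_choices for r in results}
    if len(n_choices) > 1:
        raise ValueError(
            f"results were fitted on different numbers of choices: {sorted(n_choices)}"
        )
    if labels is None:
        labels = [f"{r.model_kind}_{i}" for i, r in enumerate(results)]
    rows = [
        {
            "label": lab,
            "model_kind": r.model_kind,
            "loglik": r.loglik,
            "k": r.k,
            "bic": r.bic,
        }
        for lab, r in zip(labels, results)
    ]
    table = pd.DataFrame(rows).sort_values(
        ["bic", "k"], kind="stable", ignore_index=True
    )
    table["selected"] = False
    table.loc[0, "selected"] = True
    return table
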