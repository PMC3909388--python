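"""Replicated simulation experiments over the matching stage.

The headline quantity is the *review burden*: how many ineligible control
charts must be reviewed per case before the target match ratio is reached.
Under iid per-review eligibility p and an unbounded candidate pool this is
negative binomial with mean r(1-p)/p for match ratio r; finite pools truncate
the tail slightly.
"""
from __future__ import annotations

import dataclasses
import random

from ._rand import derive_seed
from .config import GeneratorConfig
from .generate import generate_control_stream, realize_case_disposition
from .matching import run_matching


def simulate_review_burden(
    config: GeneratorConfig,
    n_cases: int = 41,
    n_replicates: int = 500,
    seed: int = 0,
    pool_cap: int | None = None,
    replacement: bool = False,
) -> list[int]:
    """Per-case ineligible review counts over replicated cohort matchings.

    Each replicate realizes ``n_cases`` includable cases and runs the full
    sequential-review matching against per-case candidate streams with
    ``pool_cap`` candidates each (``None``: the configured pool cap). Returns
    the flat list of ``n_cases * n_replicates`` counts.
    """
    spec = dataclasses.replace(config.match_spec, replacement=replacement)
    counts: list[int] = []
    for rep in range(n_replicates):
        case_rng = random.Random(derive_seed(seed, "review-burden-cases", rep))
        cases = [
            realize_case_disposition(
                "INCLUDED", config, case_rng, f"R{rep:04d}-P{i:03d}"
            )[0]
            for i in range(n_cases)
        ]

        def source(case, rng):
            return generate_control_stream(case, config, rng, pool_cap=pool_cap)

        match_rng = random.Random(derive_seed(seed, "review-burden-match", rep))
        results, _, _ = run_matching(cases, source, config.criteria, spec, match_rng)
        counts.extend(r.n_reviewed_ineligible for r in results)
    return counts
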