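"""Descriptor importance by frequency of use across cross-validation models.

Every model trained during repeated k-fold CV uses a subset of the
descriptors in its split nodes.  A descriptor's importance is the fraction of
models in which it was used at least once; descriptors used in more than 90%
of the models are selected as the informative set.  Frequency-of-use is a
natural importance measure for a Decision Forest, where disjoint pools force
each model to spread its splits across independent descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .validation import CVResult

__all__ = ["DescriptorFrequency", "descriptor_frequencies", "frequency_frame",
           "select_informative"]


@dataclass(frozen=True)
class DescriptorFrequency:
    descriptor_name: str
    n_models_used: int
    fraction: float


def descriptor_frequencies(cv_result: CVResult) -> list[DescriptorFrequency]:
    """Rank descriptors by the fraction of CV models whose trees split on them.

    A descriptor counts as used in a model iff it appears in at least one
    split node of at least one of the model's trees (pool membership alone
    does not count).  Sorted by fraction descending, name ascending on ties.
    Unused descriptors are not implied — callers wanting zero rows should pass
    the full descriptor list to :func:`frequency_frame`.
    """
    if not cv_result.descriptor_usage:
        raise ValueError("CV result carries no descriptor usage records")
    total = cv_result.n_models
    counts: dict[str, int] = {}
    for used in cv_result.descriptor_usage:
        for name in used:
            counts[name] = counts.get(name, 0) + 1
    freqs = [DescriptorFrequency(name, n, n / total) for name, n in counts.items()]
    return sorted(freqs, key=lambda f: (-f.fraction, f.descriptor_name))


def frequency_frame(
    cv_result: CVResult, all_names: list[str] | None = None
) -> pd.DataFrame:
    """Ranked frequency table; ``all_names`` adds zero-frequency rows for unused descriptors."""
    freqs = descriptor_frequencies(cv_result)
    seen = {f.descriptor_name for f in freqs}
    if all_names is not None:
        freqs += [DescriptorFrequency(n, 0, 0.0) for n in sorted(set(all_names) - seen)]
    df = pd.DataFrame(
        [{"descriptor_name": f.descriptor_name, "n_models_used": f.n_models_used,
          "fraction": f.fraction} for f in freqs]
    )
    df.insert(0, "rank", range(1, len(df) + 1))
    return df


def select_informative(
    frequencies: list[DescriptorFrequency], threshold_fraction: float = 0.9
) -> list[str]:
    """Names used in strictly more than ``threshold_fraction`` of the models."""
    if not frequencies:
        raise ValueError("empty frequency list")
    return [f.descriptor_name for f in frequencies if f.fraction > threshold_fraction]
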