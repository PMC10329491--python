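"""Expression-signature channel: consensus-signature lookup for drugs/targets.

A drug is represented by its compound-perturbation consensus signature; a
target by the gene-overexpression signature when the interaction activates
the target and by the gene-knockdown signature when it inhibits it.  Lookups
are exact rows of the stored matrices — no interpolation or rescaling — and a
missing row signals that the expression modality is unavailable for that
entity rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SignatureStore", "drug_signature", "target_signature",
           "UNKNOWN_DIRECTION_POLICIES"]

#: how to pick a target signature when the interaction direction is unknown
#: (negatives and unlabeled pairs). Knockdown ("xpr") is the default because
#: inhibition is by far the majority direction among labeled interactions.
UNKNOWN_DIRECTION_POLICIES = ("xpr", "oe", "both-averaged")


@dataclass
class SignatureStore:
    """Three row-keyed signature matrices over one shared gene panel."""

    m_d: pd.DataFrame    # compound perturbation, |D| x G
    m_oe: pd.DataFrame   # gene overexpression, |OE| x G
    m_xpr: pd.DataFrame  # gene knockdown, |XPR| x G

    def __post_init__(self):
        panels = {tuple(m.columns) for m in (self.m_d, self.m_oe, self.m_xpr)}
        if len(panels) != 1:
            raise ValueError("signature matrices must share one gene panel")
        for m in (self.m_d, self.m_oe, self.m_xpr):
            if not np.isfinite(m.to_numpy(dtype=float)).all():
                raise ValueError("signature matrices must be finite")

    @property
    def gene_panel(self) -> list[str]:
        return list(self.m_d.columns)

    @property
    def n_genes(self) -> int:
        return self.m_d.shape[1]

    def has_drug(self, drug_id: str) -> bool:
        return drug_id in self.m_d.index

    def has_target(self, target_id: str, direction: str,
                   unknown_policy: str = "xpr") -> bool:
        return target_signature(target_id, direction, self,
                                unknown_policy=unknown_policy) is not None


def drug_signature(drug_id: str, store: SignatureStore) -> np.ndarray | None:
    """Exact compound-signature row, or None if the modality is unavailable."""
    if drug_id not in store.m_d.index:
        return None
    return store.m_d.loc[drug_id].to_numpy(dtype=float)


def target_signature(target_id: str, direction: str, store: SignatureStore,
                     unknown_policy: str = "xpr") -> np.ndarray | None:
    """Direction-routed target signature row.

    activate -> overexpression matrix; inhibit -> knockdown matrix; unknown
    -> the configured policy ("xpr", "oe", or the mean of both rows).
    Returns None when the required row(s) are absent.
    """
    if unknown_policy not in UNKNOWN_DIRECTION_POLICIES:
        raise ValueError(f"unknown_policy must be one of "
                         f"{UNKNOWN_DIRECTION_POLICIES}, got {unknown_policy!r}")

    def row(frame: pd.DataFrame) -> np.ndarray | None:
        if target_id not in frame.index:
            return None
        return frame.loc[target_id].to_numpy(dtype=float)

    if direction == "activate":
        return row(store.m_oe)
    if direction == "inhibit":
        return row(store.m_xpr)
    if direction == "unknown":
        if unknown_policy == "xpr":
            return row(store.m_xpr)
        if unknown_policy == "oe":
            return row(store.m_oe)
        a, b = row(store.m_oe), row(store.m_xpr)
        if a is None or b is None:
            return None
        return (a + b) / 2.0
    raise ValueError(f"invalid direction {direction!r}")
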