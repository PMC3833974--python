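"""Derivation of the 11 allergy phenotypes with restricted reference groups.

Atopic sensitization is allergen-specific IgE >= 0.35 kU/L against inhalant
and/or food allergens (strict variant: >= 3.5 kU/L). Asthma is a doctor's
diagnosis ever; current asthma additionally requires wheeze in the last 12
months. The allergic/non-allergic disease subtypes split the diseased
children by sensitization and share one restricted reference group: children
with neither the disease nor sensitization. Everyone else is EXCLUDED from
that phenotype (retained in files, dropped from computation).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dtable import AFFECTED, EXCLUDED, UNAFFECTED

PHENOTYPES = (
    "asthma",
    "allergic_asthma",
    "nonallergic_asthma",
    "current_asthma",
    "wheeze",
    "eczema",
    "allergic_eczema",
    "nonallergic_eczema",
    "rhinoconjunctivitis",
    "sens_0.35",
    "sens_3.5",
)

SENS_THRESHOLD = 0.35
SENS_STRICT_THRESHOLD = 3.5


def _status(affected, unaffected) -> np.ndarray:
    out = np.full(len(affected), EXCLUDED, dtype=object)
    out[np.asarray(unaffected, dtype=bool)] = UNAFFECTED
    out[np.asarray(affected, dtype=bool)] = AFFECTED
    return out


def derive_phenotypes(records) -> pd.DataFrame:
    """Phenotype assignments (affected/unaffected/EXCLUDED) per record.

    ``records`` is a raw-health DataFrame (columns asthma_dx_ever, wheeze_12m,
    eczema_dx, rhino_symptoms_12m, ige_inhalant, ige_food) or a list of
    RawHealthRecord. A missing ingredient excludes the record from every
    phenotype that needs it.

    The reference group for current asthma is all non-asthmatics; asthmatics
    without recent wheeze are EXCLUDED (configurable choice documented in the
    methods note).
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(
            {
                "asthma_dx_ever": [r.asthma_dx_ever for r in records],
                "wheeze_12m": [r.wheeze_12m for r in records],
                "eczema_dx": [r.eczema_dx for r in records],
                "rhino_symptoms_12m": [r.rhino_symptoms_12m for r in records],
                "ige_inhalant": [r.ige_inhalant for r in records],
                "ige_food": [r.ige_food for r in records],
            }
        )
    df = records
    idx = df.index

    def flag(col: str) -> tuple[np.ndarray, np.ndarray]:
        known = df[col].notna().to_numpy()
        val = df[col].fillna(False).astype(bool).to_numpy()
        return val & known, known

    asthma, asthma_known = flag("asthma_dx_ever")
    wheeze, wheeze_known = flag("wheeze_12m")
    eczema, eczema_known = flag("eczema_dx")
    rhino, rhino_known = flag("rhino_symptoms_12m")
    ige_known = (df["ige_inhalant"].notna() & df["ige_food"].notna()).to_numpy()
    ige_max = df[["ige_inhalant", "ige_food"]].max(axis=1).to_numpy()
    sens = ige_known & (ige_max >= SENS_THRESHOLD)
    sens_strict = ige_known & (ige_max >= SENS_STRICT_THRESHOLD)

    out = pd.DataFrame(index=idx)
    out["asthma"] = _status(asthma & asthma_known, ~asthma & asthma_known)

    both = asthma_known & ige_known
    reference = both & ~asthma & ~sens
    out["allergic_asthma"] = _status(both & asthma & sens, reference)
    out["nonallergic_asthma"] = _status(both & asthma & ~sens, reference)

    ca_known = asthma_known & wheeze_known
    out["current_asthma"] = _status(ca_known & asthma & wheeze, asthma_known & ~asthma)

    out["wheeze"] = _status(wheeze & wheeze_known, ~wheeze & wheeze_known)

    out["eczema"] = _status(eczema & eczema_known, ~eczema & eczema_known)
    eboth = eczema_known & ige_known
    ereference = eboth & ~eczema & ~sens
    out["allergic_eczema"] = _status(eboth & eczema & sens, ereference)
    out["nonallergic_eczema"] = _status(eboth & eczema & ~sens, ereference)

    out["rhinoconjunctivitis"] = _status(rhino & rhino_known, ~rhino & rhino_known)
    out["sens_0.35"] = _status(sens, ige_known & ~sens)
    out["sens_3.5"] = _status(sens_strict, ige_known & ~sens_strict)
    return out


def phenotype_counts(assignments: pd.DataFrame) -> pd.DataFrame:
    """Affected/unaffected/excluded tallies per phenotype (rows sum to N)."""
    rows = []
    for ph in assignments.columns:
        col = assignments[ph]
        rows.append(
            {
                "phenotype": ph,
                "affected": int((col == AFFECTED).sum()),
                "unaffected": int((col == UNAFFECTED).sum()),
                "excluded": int((col == EXCLUDED).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("phenotype")
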