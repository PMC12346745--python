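"""Two-tier diagnostic taxonomy used by PTB-XL-style corpora.

PTB-XL annotates each record with SCP statement codes. The diagnostic axis of
those statements rolls up into five superclasses (NORM, CD, HYP, MI, STTC)
refined into 23 subclasses (e.g. IMI — inferior myocardial infarction,
CLBBB — complete left bundle branch block). The tables below are the
canonical roll-up used everywhere in this package; order matters because it
doubles as the deterministic tie-break for top-k subclass selection.
"""

from __future__ import annotations

# Superclasses in the order they are reported (NORM first, then disease
# superclasses in the order used by the 5-class task).
SUPERCLASSES: tuple[str, ...] = ("NORM", "MI", "CD", "STTC", "HYP")

# subclass -> (superclass, description), in taxonomy order.
SUBCLASSES: dict[str, tuple[str, str]] = {
    "NORM": ("NORM", "Normal ECG"),
    # Conduction disturbance
    "LAFB/LPFB": ("CD", "Left anterior / left posterior fascicular block"),
    "IRBBB": ("CD", "Incomplete right bundle branch block"),
    "ILBBB": ("CD", "Incomplete left bundle branch block"),
    "CLBBB": ("CD", "Complete left bundle branch block"),
    "CRBBB": ("CD", "Complete right bundle branch block"),
    "_AVB": ("CD", "AV block"),
    "IVCD": ("CD", "Non-specific intraventricular conduction disturbance"),
    "WPW": ("CD", "Wolff-Parkinson-White syndrome"),
    # Hypertrophy
    "LVH": ("HYP", "Left ventricular hypertrophy"),
    "RVH": ("HYP", "Right ventricular hypertrophy"),
    "LAO/LAE": ("HYP", "Left atrial overload/enlargement"),
    "RAO/RAE": ("HYP", "Right atrial overload/enlargement"),
    "SEHYP": ("HYP", "Septal hypertrophy"),
    # Myocardial infarction
    "AMI": ("MI", "Anterior myocardial infarction"),
    "IMI": ("MI", "Inferior myocardial infarction"),
    "LMI": ("MI", "Lateral myocardial infarction"),
    "PMI": ("MI", "Posterior myocardial infarction"),
    # ST/T change
    "ISCA": ("STTC", "Ischemic in anterior leads"),
    "ISCI": ("STTC", "Ischemic in inferior leads"),
    "ISC_": ("STTC", "Non-specific ischemic"),
    "STTC": ("STTC", "ST-T changes"),
    "NST_": ("STTC", "Non-specific ST changes"),
}

# Alternate spellings occasionally seen for the same statements.
SUBCLASS_ALIASES: dict[str, str] = {
    "IVCB": "IVCD",
    "RHV": "RVH",
}

#: Order index of every subclass (taxonomy order, used as tie-break).
SUBCLASS_ORDER: dict[str, int] = {c: i for i, c in enumerate(SUBCLASSES)}

#: The 12 standard lead names in storage order.
LEAD_NAMES: tuple[str, ...] = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)


def canonical_subclass(code: str) -> str:
    """Resolve aliases to the canonical subclass code."""
    return SUBCLASS_ALIASES.get(code, code)


def superclass_of(subclass: str) -> str:
    """Superclass a subclass rolls up into.

    Raises ``KeyError`` for codes outside the diagnostic taxonomy.
    """
    return SUBCLASSES[canonical_subclass(subclass)][0]


def subclasses_of(superclass: str) -> list[str]:
    """All subclasses under a superclass, in taxonomy order."""
    if superclass not in SUPERCLASSES:
        raise KeyError(f"unknown superclass {superclass!r}")
    return [c for c, (s, _) in SUBCLASSES.items() if s == superclass]
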