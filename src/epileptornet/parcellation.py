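"""Desikan-Killiany-based whole-brain parcellation (84 regions).

Per hemisphere: the 34 Desikan-Killiany cortical regions plus the cerebellar
cortex (counted with the cortical sheet here, 70 "cortical" labels in total)
and 7 subcortical gray-matter structures (14 in total).  Region abbreviations
follow the usual clinical shorthand (e.g. ``rLOFC`` = right lateral
orbito-frontal cortex); the mapping is best-effort where FreeSurfer spelling
and clinical shorthand diverge.
"""

from __future__ import annotations

_DK_CORTICAL = [
    ("bankssts", "BSTS"),
    ("caudalanteriorcingulate", "CACG"),
    ("caudalmiddlefrontal", "CMFG"),
    ("cuneus", "Cun"),
    ("entorhinal", "EntC"),
    ("fusiform", "FuG"),
    ("inferiorparietal", "IPC"),
    ("inferiortemporal", "ITG"),
    ("isthmuscingulate", "IstC"),
    ("lateraloccipital", "LOCC"),
    ("lateralorbitofrontal", "LOFC"),
    ("lingual", "LgG"),
    ("medialorbitofrontal", "MOFC"),
    ("middletemporal", "MTG"),
    ("parahippocampal", "PHiG"),
    ("paracentral", "ParaC"),
    ("parsopercularis", "Pop"),
    ("parsorbitalis", "POr"),
    ("parstriangularis", "PTr"),
    ("pericalcarine", "PC"),
    ("postcentral", "PoG"),
    ("posteriorcingulate", "PCG"),
    ("precentral", "PrG"),
    ("precuneus", "PCunC"),
    ("rostralanteriorcingulate", "RACG"),
    ("rostralmiddlefrontal", "RMFG"),
    ("superiorfrontal", "SFG"),
    ("superiorparietal", "SPC"),
    ("superiortemporal", "STG"),
    ("supramarginal", "SMG"),
    ("frontalpole", "FP"),
    ("temporalpole", "TmP"),
    ("transversetemporal", "TrTG"),
    ("insula", "Ins"),
    ("cerebellumcortex", "CerC"),
]

_SUBCORTICAL = [
    ("thalamus", "Tha"),
    ("caudate", "Cd"),
    ("putamen", "Pu"),
    ("pallidum", "Pal"),
    ("hippocampus", "Hi"),
    ("amygdala", "Amg"),
    ("accumbens", "NAcc"),
]


def load_parcellation() -> list[str]:
    """Return the ordered 84 region labels, left hemisphere first.

    Labels are ``lh-``/``rh-`` prefixed; cortical regions come before the
    subcortical structures within each hemisphere.
    """
    labels: list[str] = []
    for hemi in ("lh", "rh"):
        labels += [f"{hemi}-{name}" for name, _ in _DK_CORTICAL]
        labels += [f"{hemi}-{name}" for name, _ in _SUBCORTICAL]
    return labels


def cortical_labels() -> list[str]:
    return [lab for lab in load_parcellation()
            if lab.split("-", 1)[1] in {n for n, _ in _DK_CORTICAL}]


def subcortical_labels() -> list[str]:
    return [lab for lab in load_parcellation()
            if lab.split("-", 1)[1] in {n for n, _ in _SUBCORTICAL}]


_ABBREV = {abbr: name for name, abbr in _DK_CORTICAL + _SUBCORTICAL}


def resolve_abbreviation(abbrev: str) -> str:
    """Resolve a clinical shorthand like ``rLOFC`` to a parcellation label.

    The first character encodes the hemisphere (``l``/``r``); the remainder
    is the region abbreviation.
    """
    if len(abbrev) < 2 or abbrev[0] not in "lr":
        raise KeyError(f"cannot parse hemisphere from {abbrev!r}")
    hemi = "lh" if abbrev[0] == "l" else "rh"
    body = abbrev[1:]
    if body not in _ABBREV:
        raise KeyError(f"unknown region abbreviation {body!r}")
    return f"{hemi}-{_ABBREV[body]}"
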