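"""Registry of the 20 named white-matter tracts.

The set mirrors the standard automated-tractometry inventory: nine
bilateral tract pairs plus the anterior and posterior corpus callosum.
Short codes follow the common neuroimaging abbreviations (LTR = left
thalamic radiation, ACC/PCC = anterior/posterior corpus callosum, ...).
"""

from __future__ import annotations

#: Bilateral tract stems, expanded to left/right below.
_BILATERAL = (
    ("TR", "thalamic radiation"),
    ("CST", "corticospinal tract"),
    ("CC", "cingulum cingulate"),
    ("CH", "cingulum hippocampus"),
    ("IFOF", "inferior fronto-occipital fasciculus"),
    ("ILF", "inferior longitudinal fasciculus"),
    ("SLF", "superior longitudinal fasciculus"),
    ("UF", "uncinate fasciculus"),
    ("AF", "arcuate fasciculus"),
)

#: The 20 tract codes, fixed order (left/right pairs, then callosal parts).
TRACTS: tuple[str, ...] = tuple(
    f"{side}{code}" for code, _ in _BILATERAL for side in ("L", "R")
) + ("ACC", "PCC")

#: Human-readable names keyed by code.
TRACT_NAMES: dict[str, str] = {
    **{
        f"{side}{code}": f"{'left' if side == 'L' else 'right'} {name}"
        for code, name in _BILATERAL
        for side in ("L", "R")
    },
    "ACC": "anterior corpus callosum",
    "PCC": "posterior corpus callosum",
}

#: The six tracts where hyperintensity burden concentrates in mild TBI:
#: bilateral thalamic radiation, bilateral cingulum cingulate, and the
#: anterior/posterior corpus callosum.
AFFECTED_TRACTS: tuple[str, ...] = ("LTR", "RTR", "LCC", "RCC", "ACC", "PCC")

assert len(TRACTS) == 20 and len(set(TRACTS)) == 20
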