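"""Reference datasets shipped with the package.

Currently one dataset: the published interface composition of the
NRP1-b1 / KDKPPR peptide complex, used as the worked example for the
contact-enrichment arithmetic (the surface compositions and observed
contact percentages are the *inputs*; enrichment ratios are recomputed
from them).
"""

from __future__ import annotations

import json
from importlib import resources


def _unkey(d: dict[str, float]) -> dict[tuple[str, str], float]:
    return {tuple(k.split("|")): v for k, v in d.items()}


def nrp1b1_kdkppr_contact_data() -> dict:
    """Published interface statistics of the NRP1-b1/KDKPPR complex.

    Returns a dict with:

    ``surface_peptide``, ``surface_protein``
        type -> % of that side's interface area (one-decimal as printed);
    ``contacts``
        unordered type pair -> % of interface area;
    ``published_enrichment``, ``published_grouped``
        the published ratios and the hydrophobic/hydrophilic block, kept
        for cross-checks (they are outputs, not inputs, of the method).
    """
    raw = json.loads(
        resources.files("contactzones.data")
        .joinpath("nrp1b1_kdkppr_contacts.json")
        .read_text()
    )
    out = dict(raw)
    out["contacts"] = _unkey(raw["contacts"])
    out["published_enrichment"] = _unkey(raw["published_enrichment"])
    pg = dict(raw["published_grouped"])
    pg["contacts"] = _unkey(pg["contacts"])
    pg["enrichment"] = _unkey(pg["enrichment"])
    out["published_grouped"] = pg
    return out
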