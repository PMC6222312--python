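"""Worked-example input data: the ketosteroid-isomerase decomposition.

Published per-residue time-average electric fields (MV/cm, Amber-ff99SB
charge model over QM/MM-sampled configurations) exerted on the carbonyl
probe of the bound product analogue 19-nortestosterone, for wild-type
ketosteroid isomerase and three active-site mutants.  Residues 16 and 103
hydrogen-bond the probe carbonyl directly; residue 40 is the catalytic base.

These numbers are *inputs* to the analytics layer (decomposition sums and
joint-contribution percentages); the package recomputes everything derived
from them.
"""

from __future__ import annotations

__all__ = ["ksi_residue_fields", "KSI_VARIANTS", "KSI_KEY_RESIDUES"]

KSI_VARIANTS = ("WT", "D103N", "Y16S", "D103L")
KSI_KEY_RESIDUES = ("RES 16", "RES 103")

#: Per-variant source-group fields, MV/cm.  "total" is the field exerted by
#: all protein residues plus solvent; "solvent" the solvent share.
_KSI_FIELDS = {
    "WT":    {"RES 16": -47.0, "RES 103": -52.0, "RES 40": -26.0,
              "total": -124.0, "solvent": 7.0},
    "D103N": {"RES 16": -46.0, "RES 103": -36.0, "RES 40": -29.0,
              "total": -93.0, "solvent": 10.0},
    "Y16S":  {"RES 16": -2.0, "RES 103": -51.0, "RES 40": -22.0,
              "total": -74.0, "solvent": 8.0},
    "D103L": {"RES 16": -45.0, "RES 103": -4.0, "RES 40": -23.0,
              "total": -66.0, "solvent": 9.0},
}


def ksi_residue_fields(variant: str) -> dict[str, float]:
    """Group -> field (MV/cm) map for one KSI variant (WT, D103N, Y16S,
    D103L)."""
    try:
        return dict(_KSI_FIELDS[variant])
    except KeyError:
        raise KeyError(f"unknown variant {variant!r}; "
                       f"choose from {KSI_VARIANTS}") from None
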