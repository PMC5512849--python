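"""Strain specifications and in-silico gene knockouts.

Knockout semantics:

* ``fnr``  — Fnr activity is identically zero at every oxygen level; all Fnr
  regulation edges become inert (activated targets fall to baseline, repressed
  targets are de-repressed).
* ``arcA`` — ArcA activity is identically zero, same edge semantics.
* ``pfl``  — pyruvate formate-lyase carries no flux (v_max set to zero), so
  no formate is ever formed.

Any other gene named on a reaction in the network may be knocked out the same
way (its reaction v_max is zeroed).  Knockouts are idempotent and commute.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .network import MetabolicNetwork
from .parameters import ParameterSet

__all__ = ["StrainSpec", "apply_knockout", "WT"]


@dataclass(frozen=True)
class StrainSpec:
    name: str
    knockouts: frozenset[str] = field(default_factory=frozenset)

    @classmethod
    def from_name(cls, name: str) -> "StrainSpec":
        """'WT' or a strain named after its knockouts, e.g. 'pfl' or 'fnr+arcA'."""
        if name.upper() in ("WT", "WILDTYPE", "WILD-TYPE"):
            return cls(name="WT")
        genes = frozenset(g.strip() for g in name.replace("+", ",").split(",") if g.strip())
        return cls(name=name, knockouts=genes)


WT = StrainSpec(name="WT")


def apply_knockout(
    network: MetabolicNetwork, params: ParameterSet, strain: StrainSpec
) -> tuple[MetabolicNetwork, ParameterSet]:
    """Return (network, params) with the strain's knockouts applied.

    The network object is returned unchanged (regulation edges stay in the
    table; they are silenced through the TF activity scale), the parameter set
    is copied with TF scales and/or v_max values zeroed.
    """
    params = params.copy()
    tf_genes = {"fnr": "Fnr", "arca": "ArcA"}
    gene_to_rxn = {r.gene: r for r in network.reactions.values() if r.gene}
    for gene in sorted(strain.knockouts):
        key = gene.lower()
        if key in tf_genes:
            params.tf_scale[tf_genes[key]] = 0.0
        elif gene in gene_to_rxn:
            params.values[gene_to_rxn[gene].rate_law.vmax] = 0.0
        else:
            raise ValueError(
                f"unknown gene {gene!r}: not a transcription factor and not carried "
                "by any reaction in the network"
            )
    return network, params
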