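"""Ventral-marker expression extent and gastrulation staging from embryo measurements.

Three dorsal–ventral lengths are measured on each lateral-view embryo image:
the extent of the szlA (ventral marker) expression domain (szl_dv), the
embryo diameter (emb_dv), and the blastopore diameter (bp_dv).  The marker
extent is expressed as szl_dv/emb_dv x 100; gastrulation stage as percent
blastopore closure, (emb_dv - bp_dv)/bp_dv x 100.  Staging windows select
embryos between given closure percentages (strict bounds).

The closure formula divides by the blastopore diameter, so small blastopores
give values above 100%; an alternative denominator (the embryo diameter,
which caps closure at 100%) is available behind an explicit flag.
"""

from __future__ import annotations

from dataclasses import dataclass

TREATMENTS = ("control", "chdB1_mRNA", "chdB2_mRNA")


@dataclass(frozen=True)
class EmbryoMeasurement:
    embryo_id: str
    treatment: str
    szl_dv: float
    emb_dv: float
    bp_dv: float

    def __post_init__(self) -> None:
        if self.emb_dv <= 0:
            raise ValueError("emb_dv must be positive")
        if not 0 <= self.szl_dv <= self.emb_dv:
            raise ValueError("szl_dv must lie in [0, emb_dv]")
        if not 0 < self.bp_dv <= self.emb_dv:
            raise ValueError("bp_dv must lie in (0, emb_dv]")


def szl_proportion(m: EmbryoMeasurement) -> float:
    """Extent of the szlA expression domain as a percentage of embryo diameter."""
    return m.szl_dv / m.emb_dv * 100.0


def blastopore_closure(m: EmbryoMeasurement, denominator: str = "bp") -> float:
    """Percent blastopore closure.

    ``denominator='bp'`` computes (emb_dv - bp_dv)/bp_dv x 100 (the assay's
    printed definition); ``denominator='emb'`` divides by emb_dv instead,
    which bounds the value by 100.
    """
    if denominator == "bp":
        return (m.emb_dv - m.bp_dv) / m.bp_dv * 100.0
    if denominator == "emb":
        return (m.emb_dv - m.bp_dv) / m.emb_dv * 100.0
    raise ValueError("denominator must be 'bp' or 'emb'")


def stage_window(
    measurements: list[EmbryoMeasurement],
    low: float = 20.0,
    high: float = 80.0,
    denominator: str = "bp",
) -> list[EmbryoMeasurement]:
    """Embryos strictly inside the (low, high) percent-closure window."""
    if low >= high:
        raise ValueError("low must be below high")
    return [
        m for m in measurements if low < blastopore_closure(m, denominator) < high
    ]
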