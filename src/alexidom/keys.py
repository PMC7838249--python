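"""Instrument scoring keys and clinical cut-offs.

The three self-report instruments are scored from fixed published keys:

* **AQ** (Autism-Spectrum Quotient): 50 items answered 1 = agree … 4 =
  disagree. Each item is dichotomised to 1 when endorsed in the autism
  direction (responses 1–2 on agree-keyed items, 3–4 on disagree-keyed
  items) and the 0/1 values are summed (range 0–50). Scores > 32 flag
  pronounced autism traits.
* **TAS-20** (Toronto Alexithymia Scale): 20 items answered 1–5. Items
  4, 5, 10, 18, 19 are reverse-keyed (r -> 6 - r). Subscales: DIF
  (difficulties identifying feelings, 7 items), DDF (difficulties
  describing feelings, 5 items), EOT (externally oriented thinking,
  8 items). Total >= 61 flags clinically relevant alexithymia.
* **BDI** (Beck Depression Inventory): 21 items scored 0–3, summed
  (range 0–63). 11–17 = mild-to-moderate band, >= 18 = clinical band.

The keys live here as plain data so a study using a translated or
re-keyed instrument can swap them without touching scoring logic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

# AQ items where "agree" (response 1 or 2) is the autism-keyed direction.
# Standard published key; the remaining 26 items are disagree-keyed.
AQ_AGREE_KEYED: frozenset[int] = frozenset(
    {2, 4, 5, 6, 7, 9, 12, 13, 16, 18, 19, 20, 21, 22, 23, 26, 33, 35,
     39, 41, 42, 43, 45, 46}
)

TAS_REVERSE_ITEMS: frozenset[int] = frozenset({4, 5, 10, 18, 19})
TAS_DIF_ITEMS: tuple[int, ...] = (1, 3, 6, 7, 9, 13, 14)
TAS_DDF_ITEMS: tuple[int, ...] = (2, 4, 11, 12, 17)
TAS_EOT_ITEMS: tuple[int, ...] = (5, 8, 10, 15, 16, 18, 19, 20)

AQ_N_ITEMS = 50
TAS_N_ITEMS = 20
BDI_N_ITEMS = 21

AQ_CUTOFF = 32        # flag is strict: score > 32
TAS_CUTOFF = 61       # flag is inclusive: total >= 61
BDI_MILD_LOW = 11     # 11 <= BDI <= 17 -> mild-moderate
BDI_CLINICAL = 18     # BDI >= 18 -> clinical


@dataclass(frozen=True)
class InstrumentKeys:
    """Editable bundle of scoring keys and cut-offs.

    ``aq_agree_keyed`` holds 1-based AQ item numbers whose *agree* pole
    (responses 1–2) scores a point; ``tas_reverse`` holds 1-based TAS-20
    items mapped r -> 6 - r before subscale summation.
    """

    aq_agree_keyed: frozenset[int] = AQ_AGREE_KEYED
    tas_reverse: frozenset[int] = TAS_REVERSE_ITEMS
    tas_dif: tuple[int, ...] = TAS_DIF_ITEMS
    tas_ddf: tuple[int, ...] = TAS_DDF_ITEMS
    tas_eot: tuple[int, ...] = TAS_EOT_ITEMS
    aq_cutoff: int = AQ_CUTOFF
    tas_cutoff: int = TAS_CUTOFF
    bdi_mild_low: int = BDI_MILD_LOW
    bdi_clinical: int = BDI_CLINICAL

    def __post_init__(self) -> None:
        subscales = (*self.tas_dif, *self.tas_ddf, *self.tas_eot)
        if sorted(subscales) != list(range(1, TAS_N_ITEMS + 1)):
            raise ValueError("TAS subscales must partition items 1..20")
        if not self.aq_agree_keyed <= set(range(1, AQ_N_ITEMS + 1)):
            raise ValueError("AQ key references items outside 1..50")


DEFAULT_KEYS = InstrumentKeys()
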