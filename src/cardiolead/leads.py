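"""Standard 12-lead conventions and named lead setups.

The canonical in-memory lead order used everywhere in this package is
(D1, D2, D3, aVR, aVL, aVF, V1..V6).  D1/D2/D3 are the Einthoven limb
leads (WFDB calls them I/II/III); aVR/aVL/aVF are the Goldberger
augmented leads; V1-V6 are the Wilson precordial leads.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Canonical lead order for 12-row signal arrays.
LEAD_NAMES: tuple[str, ...] = (
    "D1", "D2", "D3", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

#: Aliases accepted on input (WFDB / PTB-XL spell the limb leads I/II/III).
LEAD_ALIASES: dict[str, str] = {
    "I": "D1", "II": "D2", "III": "D3",
    "AVR": "aVR", "AVL": "aVL", "AVF": "aVF",
    **{name.upper(): name for name in LEAD_NAMES},
    **{name: name for name in LEAD_NAMES},
}


def canonical_lead(name: str) -> str:
    """Map a lead name (any accepted spelling) to its canonical form."""
    key = name.strip()
    try:
        return LEAD_ALIASES[key] if key in LEAD_ALIASES else LEAD_ALIASES[key.upper()]
    except KeyError:
        raise ValueError(f"unknown ECG lead name: {name!r}") from None


@dataclass(frozen=True)
class LeadSetup:
    """A named, ordered subset of the 12 standard leads.

    ``n_leads`` is the input dimension L of the network built for this
    setup (1 <= L <= 12).
    """

    name: str
    lead_names: tuple[str, ...]

    def __post_init__(self) -> None:
        canon = tuple(canonical_lead(n) for n in self.lead_names)
        object.__setattr__(self, "lead_names", canon)
        if not 1 <= len(canon) <= 12:
            raise ValueError("a lead setup must contain between 1 and 12 leads")
        if len(set(canon)) != len(canon):
            raise ValueError(f"duplicate leads in setup {self.name!r}")

    @property
    def n_leads(self) -> int:
        return len(self.lead_names)

    @property
    def indices(self) -> tuple[int, ...]:
        """Row indices of this setup's leads in the canonical 12-row order."""
        return tuple(LEAD_NAMES.index(n) for n in self.lead_names)


def _build_standard_setups() -> dict[str, LeadSetup]:
    setups = {
        "12lead": LeadSetup("12lead", LEAD_NAMES),
        "8lead": LeadSetup("8lead", ("D1", "D2", "V1", "V2", "V3", "V4", "V5", "V6")),
        "D1": LeadSetup("D1", ("D1",)),
    }
    for second in ("D2", "V1", "V2", "V3", "V4", "V5", "V6"):
        name = f"D1+{second}"
        setups[name] = LeadSetup(name, ("D1", second))
    return setups


#: The named setup families compared in the lead-ablation study:
#: full 12-lead, the 8 independent leads, single-lead D1, and D1 paired
#: with one additional lead.
STANDARD_SETUPS: dict[str, LeadSetup] = _build_standard_setups()


def get_setup(name_or_setup: str | LeadSetup) -> LeadSetup:
    """Resolve a setup by name ("12lead", "8lead", "D1", "D1+V3", ...)."""
    if isinstance(name_or_setup, LeadSetup):
        return name_or_setup
    try:
        return STANDARD_SETUPS[name_or_setup]
    except KeyError:
        raise ValueError(
            f"unknown lead setup {name_or_setup!r}; "
            f"known setups: {', '.join(sorted(STANDARD_SETUPS))}"
        ) from None
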