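"""Cross-species miRNA family concordance calls.

miRNAs are grouped into families by the central numeric part of their
identifiers (hsa-mir-10b and dre-mir-10a share family "10"); a family is
comparable when it has at least one member in each species.  A family is
called concordantly gained when at least one member in each species lies
in a recurrent gain and *no* member of either species lies in any
recurrent loss (the exclusivity veto), and symmetrically for losses.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .model import Biotype, GeneRecord
from .recurrence import RecurrentRegion

__all__ = ["SeedFamily", "build_families", "call_family_cna", "family_key"]

log = logging.getLogger(__name__)

# the numeric core after a mir/let token, e.g. "10" from hsa-mir-10b or
# "7" from let-7a; species prefixes and letter/locus suffixes are ignored
_KEY_RE = re.compile(r"(?:mir|let)-?(\d+)", re.IGNORECASE)


def family_key(mirna_id: str) -> str | None:
    """Extract the family key (numeric identifier core) from a miRNA id."""
    m = _KEY_RE.search(mirna_id)
    return m.group(1) if m else None


@dataclass
class SeedFamily:
    """A cross-species miRNA correspondence group."""

    key: str
    human_members: list[GeneRecord] = field(default_factory=list)
    fish_members: list[GeneRecord] = field(default_factory=list)

    @property
    def comparable(self) -> bool:
        return bool(self.human_members) and bool(self.fish_members)


def build_families(
    human_mirnas: Sequence[GeneRecord],
    fish_mirnas: Sequence[GeneRecord],
) -> list[SeedFamily]:
    """Group miRNA gene records into families by identifier numeric core.

    Records whose id has no digit run are skipped with a warning.  Families
    lacking members in either species are dropped (not comparable).
    """
    families: dict[str, SeedFamily] = {}
    for records, attr in ((human_mirnas, "human_members"), (fish_mirnas, "fish_members")):
        for rec in records:
            if rec.biotype != Biotype.MIRNA:
                continue
            key = family_key(rec.gene_id)
            if key is None:
                log.warning("miRNA id %s has no numeric core; skipped", rec.gene_id)
                continue
            fam = families.setdefault(key, SeedFamily(key=key))
            getattr(fam, attr).append(rec)
    return sorted(
        (f for f in families.values() if f.comparable), key=lambda f: int(f.key)
    )


def _member_state(
    member: GeneRecord, regions: Sequence[RecurrentRegion]
) -> set[str]:
    """Polarities of the recurrent regions containing the member's midpoint."""
    return {
        r.polarity
        for r in regions
        if r.contains(member.chromosome, member.midpoint)
    }


def call_family_cna(
    families: Sequence[SeedFamily],
    human_regions: Sequence[RecurrentRegion],
    fish_regions: Sequence[RecurrentRegion],
) -> pd.DataFrame:
    """Call families concordantly gained / lost under the exclusivity rule.

    A family is called for polarity P iff at least one human member and at
    least one fish member lie in a recurrent region of polarity P, and no
    member of either species lies in any region of the opposite polarity.
    Returns one row per comparable family with its call ("gain", "loss" or
    "none") and the per-species polarity sets.
    """
    rows = []
    for fam in families:
        human_states: set[str] = set()
        fish_states: set[str] = set()
        for m in fam.human_members:
            human_states |= _member_state(m, human_regions)
        for m in fam.fish_members:
            fish_states |= _member_state(m, fish_regions)
        call = "none"
        for polarity in ("gain", "loss"):
            opposite = "loss" if polarity == "gain" else "gain"
            if (
                polarity in human_states
                and polarity in fish_states
                and opposite not in human_states
                and opposite not in fish_states
            ):
                call = polarity
        rows.append(
            {
                "family": fam.key,
                "n_human_members": len(fam.human_members),
                "n_fish_members": len(fam.fish_members),
                "human_states": ",".join(sorted(human_states)) or ".",
                "fish_states": ",".join(sorted(fish_states)) or ".",
                "call": call,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "family",
            "n_human_members",
            "n_fish_members",
            "human_states",
            "fish_states",
            "call",
        ],
    )
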