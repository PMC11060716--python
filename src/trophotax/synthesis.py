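"""Multi-proxy diet synthesis.

Each line of evidence (body mass, jaw mechanical advantage, FE strain,
pedal and skull morphometrics) yields a per-taxon verdict: the diets it
makes likely and unlikely.  The final diagnosis is the intersection of
the likely sets over the available *diet* proxies — pedal morphometrics
informs use of the foot rather than diet and only joins the
intersection when explicitly flagged diet-informative, and skull
morphometrics is excluded by default because its applicability to
stem birds is uncertain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["ProxyVerdict", "DietDiagnosis", "proxy_verdict", "combine_verdicts"]

#: Proxies whose likely sets vote on diet in the consensus intersection.
DIET_PROXIES = ("mass", "MA", "FEA")


@dataclass(frozen=True)
class ProxyVerdict:
    """One proxy's likely/unlikely diets (or pedal classes) for one taxon."""

    proxy: str
    taxon: str
    likely: frozenset
    unlikely: frozenset = frozenset()
    available: bool = True
    diet_informative: bool | None = None

    def __post_init__(self):
        if self.likely & self.unlikely:
            raise ValueError(
                f"{self.proxy}/{self.taxon}: likely and unlikely sets overlap"
            )


@dataclass
class DietDiagnosis:
    """Consensus diets for one taxon plus the per-proxy detail."""

    taxon: str
    consensus: frozenset
    indeterminate: bool
    per_proxy: dict = field(default_factory=dict)


def proxy_verdict(
    proxy: str,
    taxon: str,
    posterior: pd.Series | None = None,
    group_sets: dict | None = None,
    mass_groups: set | None = None,
    theta_hi: float = 0.1,
    theta_lo: float = 0.01,
    diet_informative: bool | None = None,
) -> ProxyVerdict:
    """Formalise one proxy's output as likely/unlikely sets.

    For posterior-based proxies a class is likely when its posterior is
    at least ``theta_hi`` of the maximum class posterior and unlikely
    below ``theta_lo`` of it.  For the mass proxy, pass the groups
    returned by interval classification together with ``group_sets``
    mapping each group letter to its member diets.  A missing proxy
    (``posterior`` and ``mass_groups`` both None, or an empty posterior)
    yields an unavailable verdict.
    """
    if mass_groups is not None:
        if group_sets is None:
            raise ValueError("mass verdicts need group_sets mapping letters to diets")
        likely = frozenset().union(*(frozenset(group_sets[g]) for g in mass_groups)) \
            if mass_groups else frozenset()
        universe = frozenset().union(*(frozenset(v) for v in group_sets.values()))
        return ProxyVerdict(
            proxy=proxy, taxon=taxon, likely=likely,
            unlikely=universe - likely, available=bool(mass_groups),
            diet_informative=diet_informative,
        )
    if posterior is None or len(posterior) == 0:
        return ProxyVerdict(
            proxy=proxy, taxon=taxon, likely=frozenset(), unlikely=frozenset(),
            available=False, diet_informative=diet_informative,
        )
    top = float(posterior.max())
    if top <= 0:
        return ProxyVerdict(
            proxy=proxy, taxon=taxon, likely=frozenset(), unlikely=frozenset(),
            available=False, diet_informative=diet_informative,
        )
    rel = posterior / top
    likely = frozenset(rel.index[rel >= theta_hi])
    unlikely = frozenset(rel.index[rel < theta_lo])
    return ProxyVerdict(
        proxy=proxy, taxon=taxon, likely=likely, unlikely=unlikely,
        diet_informative=diet_informative,
    )


def combine_verdicts(
    verdicts,
    include_skull: bool = False,
) -> DietDiagnosis:
    """Intersect likely diets over the available diet proxies.

    Mass, MA and FEA always vote when available; pedal morphometrics
    votes only if its verdict is flagged ``diet_informative``; skull
    morphometrics votes only with ``include_skull=True``.  An empty
    intersection is reported as indeterminate.
    """
    verdicts = list(verdicts)
    if not any(v.available for v in verdicts):
        raise ValueError("no available verdicts to combine")
    taxa = {v.taxon for v in verdicts}
    if len(taxa) != 1:
        raise ValueError(f"verdicts for multiple taxa: {sorted(taxa)}")
    (taxon,) = taxa
    voting = []
    for v in verdicts:
        if not v.available:
            continue
        if v.proxy in DIET_PROXIES:
            voting.append(v)
        elif v.proxy == "pedal_TM" and v.diet_informative:
            voting.append(v)
        elif v.proxy == "skull_TM" and include_skull:
            voting.append(v)
    if not voting:
        consensus: frozenset = frozenset()
    else:
        consensus = frozenset.intersection(*(v.likely for v in voting))
    return DietDiagnosis(
        taxon=taxon,
        consensus=consensus,
        indeterminate=len(consensus) == 0,
        per_proxy={v.proxy: v for v in verdicts},
    )
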