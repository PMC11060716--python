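"""Combine the per-proxy verdicts into the final diet diagnosis table.

Two demonstrations: (i) the six published genera, encoding each proxy's
likely/unlikely sets from the study's summary table and intersecting
them; (ii) the synthetic fossil pipeline outputs from the mass and FEA
stages, mapped through the same machinery.
"""

import pathlib

import pandas as pd

from trophotax.synthesis import ProxyVerdict, combine_verdicts, proxy_verdict

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"

MASS_TIER_DIETS = {
    "a": {"Nectarivore"},
    "b": {"Granivore", "Invertivore"},
    "c": {"Frugivore", "Generalist", "Piscivore", "Scavenger"},
    "d": {"Folivore", "TetrapodHunter"},
}

# per-proxy likely sets for the six genera (mass, jaw MA, FEA)
GENERA = {
    "Bohaiornis": (
        {"Folivore", "Frugivore", "Generalist", "Piscivore", "TetrapodHunter"},
        {"Folivore", "Generalist", "GranivoreS"},
        {"Folivore", "GranivoreH", "Nectarivore"},
    ),
    "Longusunguis": (
        {"Folivore", "Frugivore", "Generalist", "Piscivore", "TetrapodHunter"},
        {"Frugivore", "Generalist", "Invertivore", "Piscivore"},
        {"Folivore", "Frugivore", "Generalist", "GranivoreH", "GranivoreS",
         "Invertivore", "Nectarivore", "Piscivore"},
    ),
    "Parabohaiornis": (
        {"Folivore", "Frugivore", "Generalist", "Piscivore", "TetrapodHunter"},
        {"Folivore", "Generalist", "Scavenger", "GranivoreS"},
        {"Folivore", "Frugivore", "Generalist", "GranivoreH", "GranivoreS",
         "Invertivore", "Nectarivore", "Piscivore"},
    ),
    "Shenqiornis": (
        {"Folivore", "Frugivore", "Generalist", "Piscivore", "TetrapodHunter"},
        {"Folivore", "Frugivore", "Generalist", "Invertivore", "Piscivore"},
        {"Folivore", "Frugivore", "Generalist", "GranivoreH", "Invertivore",
         "Nectarivore", "Piscivore"},
    ),
    "Sulcavis": (
        {"Folivore", "Frugivore", "Generalist", "Piscivore", "TetrapodHunter"},
        {"Folivore", "Generalist", "Invertivore", "Piscivore"},
        {"Folivore", "Frugivore", "Generalist", "GranivoreH", "Invertivore",
         "Nectarivore", "Piscivore"},
    ),
    "Zhouornis": (
        {"Folivore", "Frugivore", "Generalist", "Piscivore", "Scavenger",
         "TetrapodHunter"},
        {"Frugivore", "Generalist", "Invertivore", "Piscivore"},
        {"Frugivore", "Generalist", "GranivoreH", "Nectarivore"},
    ),
}


def main():
    rows = []
    for taxon, (mass_s, ma_s, fea_s) in GENERA.items():
        verdicts = [
            ProxyVerdict("mass", taxon, frozenset(mass_s)),
            ProxyVerdict("MA", taxon, frozenset(ma_s)),
            ProxyVerdict("FEA", taxon, frozenset(fea_s)),
        ]
        d = combine_verdicts(verdicts)
        rows.append(
            {"taxon": taxon, "consensus": ", ".join(sorted(d.consensus)) or
             "indeterminate"}
        )
    table = pd.DataFrame(rows).set_index("taxon")
    table.to_csv(ROOT / "diet_diagnosis_published_encoding.csv")
    print("consensus diets (intersection over available diet proxies):")
    print(table.to_string())

    # synthetic fossil pipeline: mass tiers + FEA posteriors from stage 04
    tiers = pd.read_csv(ROOT / "fossil_mass_tiers.csv", index_col=0)
    fea_post = pd.read_csv(ROOT / "fea_fda_posteriors.csv", index_col=0)
    specimen, fossil_model = tiers.index[0], fea_post.index[0]
    v_mass = proxy_verdict(
        "mass", specimen,
        mass_groups=set(tiers.loc[specimen, "tiers"]),
        group_sets=MASS_TIER_DIETS,
    )
    v_fea = proxy_verdict("FEA", specimen, posterior=fea_post.loc[fossil_model])
    d = combine_verdicts([v_mass, v_fea])
    print(
        f"\nexample synthetic fossil ({specimen} mass + {fossil_model} strain): "
        f"consensus = {sorted(d.consensus) or 'indeterminate'}"
    )


if __name__ == "__main__":
    main()
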