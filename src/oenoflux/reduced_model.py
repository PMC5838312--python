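"""Packaged reduced central-carbon network of *Oenococcus oeni*.

The network covers the heterolactic phosphoketolase pathway, fructose
reduction to mannitol, erythritol formation, citrate degradation (with the
acetate / D-lactate / diacetyl branches), the malolactic reaction, the
malate -> oxaloacetate -> pyruvate route, serine / threonine / cysteine
degradation, F0F1-ATPase, an ATP-hydrolysis maintenance reaction, a lumped
biomass reaction, and exchange/transport reactions for every substrate and
product of interest.  ATP/ADP, NAD(P)H/NAD(P)+, CoA, protons and water are
explicit species in both compartments where relevant.

Proton bookkeeping drives the energetics: L-lactate leaves by proton
symport (the sole proton-extruding transporter), the malolactic and
acetolactate-forming reactions consume cytosolic protons, and the
F0F1-ATPase imports ``ATPASE_H_PER_ATP`` external protons per ATP made.
"""

from __future__ import annotations

import json
from importlib import resources

from .network import MetabolicNetwork, Metabolite, Reaction, _network_from_dict

#: H+ translocated inward per ATP synthesized by the F0F1-ATPase.
ATPASE_H_PER_ATP = 3

#: Exchange reaction ids of the nine substrates whose uptake rates are set
#: from experimental data.
SUBSTRATE_EXCHANGES = {
    "glucose": "EX_glc",
    "fructose": "EX_fru",
    "citrate": "EX_cit",
    "malate": "EX_mal",
    "cysteine": "EX_cys",
    "threonine": "EX_thr",
    "valine": "EX_val",
    "phenylalanine": "EX_phe",
    "serine": "EX_ser",
}

#: Exchange reaction ids of the five measured products.
PRODUCT_EXCHANGES = {
    "mannitol": "EX_man",
    "erythritol": "EX_ery",
    "L-lactate": "EX_llac",
    "D-lactate": "EX_dlac",
    "acetate": "EX_ac",
}

#: Compounds that may accumulate intracellularly between growth phases,
#: mapped to their cytosolic metabolite id.
ACCUMULATION_COMPOUNDS = {
    "mannitol": "man_c",
    "malate": "mal_c",
    "cysteine": "cys_c",
    "threonine": "thr_c",
    "phenylalanine": "phe_c",
    "valine": "val_c",
}

BIOMASS_ID = "BIOMASS"
NGAM_ID = "NGAM"
ATPASE_ID = "ATPS"

#: biomass precursor demand, mmol per gDCW.  The large ATP term lumps
#: polymerization costs with growth-associated maintenance; it reproduces
#: the very low biomass yields of this organism (~0.03 gDCW per g sugar).
BIOMASS_COMPOSITION = {
    "g6p_c": -1.1,
    "pyr_c": -0.9,
    "oaa_c": -0.3,
    "cys_c": -0.12,
    "thr_c": -0.18,
    "val_c": -0.22,
    "phe_c": -0.14,
    "ser_c": -0.16,
    "atp_c": -140.0,
    "nadph_c": -1.4,
    "h2o_c": -139.0,
    "adp_c": 140.0,
    "pi_c": 140.0,
    "nadp_c": 1.4,
    "h_c": 140.0,
}

_M = [
    # extracellular
    ("glc_e", "D-glucose", "e", "C6H12O6"),
    ("fru_e", "D-fructose", "e", "C6H12O6"),
    ("cit_e", "citrate", "e", "C6H8O7"),
    ("mal_e", "L-malate", "e", "C4H6O5"),
    ("cys_e", "L-cysteine", "e", "C3H7NO2S"),
    ("thr_e", "L-threonine", "e", "C4H9NO3"),
    ("val_e", "L-valine", "e", "C5H11NO2"),
    ("phe_e", "L-phenylalanine", "e", "C9H11NO2"),
    ("ser_e", "L-serine", "e", "C3H7NO3"),
    ("man_e", "D-mannitol", "e", "C6H14O6"),
    ("ery_e", "erythritol", "e", "C4H10O4"),
    ("llac_e", "L-lactate", "e", "C3H6O3"),
    ("dlac_e", "D-lactate", "e", "C3H6O3"),
    ("ac_e", "acetate", "e", "C2H4O2"),
    ("etoh_e", "ethanol", "e", "C2H6O"),
    ("dia_e", "diacetyl", "e", "C4H6O2"),
    ("co2_e", "carbon dioxide", "e", "CO2"),
    ("nh3_e", "ammonia", "e", "NH3"),
    ("h2s_e", "hydrogen sulfide", "e", "H2S"),
    ("o2_e", "oxygen", "e", "O2"),
    ("h_e", "proton", "e", "H"),
    ("h2o_e", "water", "e", "H2O"),
    ("pi_e", "phosphate", "e", "HPO4"),
    # cytosolic
    ("glc_c", "D-glucose", "c", "C6H12O6"),
    ("fru_c", "D-fructose", "c", "C6H12O6"),
    ("g6p_c", "D-glucose 6-phosphate", "c", "C6H13O9P"),
    ("f6p_c", "D-fructose 6-phosphate", "c", "C6H13O9P"),
    ("pg6_c", "6-phospho-D-gluconate", "c", "C6H13O10P"),
    ("ru5p_c", "D-ribulose 5-phosphate", "c", "C5H11O8P"),
    ("x5p_c", "D-xylulose 5-phosphate", "c", "C5H11O8P"),
    ("e4p_c", "D-erythrose 4-phosphate", "c", "C4H9O7P"),
    ("g3p_c", "glyceraldehyde 3-phosphate", "c", "C3H7O6P"),
    ("bpg13_c", "1,3-bisphospho-D-glycerate", "c", "C3H8O10P2"),
    ("pg3_c", "3-phospho-D-glycerate", "c", "C3H7O7P"),
    ("pep_c", "phosphoenolpyruvate", "c", "C3H5O6P"),
    ("pyr_c", "pyruvate", "c", "C3H4O3"),
    ("accoa_c", "acetyl-CoA", "c", "C23H38N7O17P3S"),
    ("acp_c", "acetyl phosphate", "c", "C2H5O5P"),
    ("acald_c", "acetaldehyde", "c", "C2H4O"),
    ("oaa_c", "oxaloacetate", "c", "C4H4O5"),
    ("alac_c", "2-acetolactate", "c", "C5H8O4"),
    ("mgx_c", "methylglyoxal", "c", "C3H4O2"),
    ("mal_c", "L-malate", "c", "C4H6O5"),
    ("cit_c", "citrate", "c", "C6H8O7"),
    ("cys_c", "L-cysteine", "c", "C3H7NO2S"),
    ("thr_c", "L-threonine", "c", "C4H9NO3"),
    ("val_c", "L-valine", "c", "C5H11NO2"),
    ("phe_c", "L-phenylalanine", "c", "C9H11NO2"),
    ("ser_c", "L-serine", "c", "C3H7NO3"),
    ("man_c", "D-mannitol", "c", "C6H14O6"),
    ("ery_c", "erythritol", "c", "C4H10O4"),
    ("llac_c", "L-lactate", "c", "C3H6O3"),
    ("dlac_c", "D-lactate", "c", "C3H6O3"),
    ("ac_c", "acetate", "c", "C2H4O2"),
    ("etoh_c", "ethanol", "c", "C2H6O"),
    ("dia_c", "diacetyl", "c", "C4H6O2"),
    ("atp_c", "ATP", "c", "C10H16N5O13P3"),
    ("adp_c", "ADP", "c", "C10H15N5O10P2"),
    ("pi_c", "phosphate", "c", "HPO4"),
    ("nad_c", "NAD+", "c", "C21H27N7O14P2"),
    ("nadh_c", "NADH", "c", "C21H28N7O14P2"),
    ("nadp_c", "NADP+", "c", "C21H28N7O17P3"),
    ("nadph_c", "NADPH", "c", "C21H29N7O17P3"),
    ("coa_c", "coenzyme A", "c", "C21H36N7O16P3S"),
    ("h_c", "proton", "c", "H"),
    ("h2o_c", "water", "c", "H2O"),
    ("co2_c", "carbon dioxide", "c", "CO2"),
    ("nh3_c", "ammonia", "c", "NH3"),
    ("h2s_c", "hydrogen sulfide", "c", "H2S"),
    ("o2_c", "oxygen", "c", "O2"),
]

BIG = 1000.0

# (id, name, stoichiometry, lb, ub, subsystem, role_tags)
_R = [
    # -- exchange reactions (positive flux = export) ----------------------
    ("EX_glc", "D-glucose exchange", {"glc_e": -1}, -BIG, BIG, "exchange", set()),
    ("EX_fru", "D-fructose exchange", {"fru_e": -1}, -BIG, BIG, "exchange", set()),
    ("EX_cit", "citrate exchange", {"cit_e": -1}, -BIG, BIG, "exchange", set()),
    ("EX_mal", "L-malate exchange", {"mal_e": -1}, -BIG, BIG, "exchange", set()),
    ("EX_cys", "L-cysteine exchange", {"cys_e": -1}, -BIG, BIG, "exchange", set()),
    ("EX_thr", "L-threonine exchange", {"thr_e": -1}, -BIG, BIG, "exchange", set()),
    ("EX_val", "L-valine exchange", {"val_e": -1}, -BIG, BIG, "exchange", set()),
    ("EX_phe", "L-phenylalanine exchange", {"phe_e": -1}, -BIG, BIG, "exchange", set()),
    ("EX_ser", "L-serine exchange", {"ser_e": -1}, -BIG, BIG, "exchange", set()),
    ("EX_man", "D-mannitol exchange", {"man_e": -1}, 0, BIG, "exchange", set()),
    ("EX_ery", "erythritol exchange", {"ery_e": -1}, 0, BIG, "exchange", set()),
    ("EX_llac", "L-lactate exchange", {"llac_e": -1}, 0, BIG, "exchange", set()),
    ("EX_dlac", "D-lactate exchange", {"dlac_e": -1}, 0, BIG, "exchange", set()),
    ("EX_ac", "acetate exchange", {"ac_e": -1}, 0, BIG, "exchange", set()),
    ("EX_etoh", "ethanol exchange", {"etoh_e": -1}, 0, BIG, "exchange", set()),
    ("EX_dia", "diacetyl exchange", {"dia_e": -1}, 0, BIG, "exchange", set()),
    ("EX_co2", "CO2 exchange", {"co2_e": -1}, 0, BIG, "exchange", set()),
    ("EX_nh3", "ammonia exchange", {"nh3_e": -1}, 0, BIG, "exchange", set()),
    ("EX_h2s", "hydrogen sulfide exchange", {"h2s_e": -1}, 0, BIG, "exchange", set()),
    # micro-aerobic: dissolved oxygen trickles in at a fixed small capacity
    ("EX_o2", "oxygen exchange", {"o2_e": -1}, -0.35, 0, "exchange", set()),
    ("EX_h", "proton exchange", {"h_e": -1}, -BIG, BIG, "exchange", set()),
    ("EX_h2o", "water exchange", {"h2o_e": -1}, -BIG, BIG, "exchange", set()),
    ("EX_pi", "phosphate exchange", {"pi_e": -1}, -BIG, BIG, "exchange", set()),
    # -- transport --------------------------------------------------------
    ("GLCt", "glucose uptake", {"glc_e": -1, "glc_c": 1}, 0, BIG, "transport", set()),
    ("FRUt", "fructose uptake", {"fru_e": -1, "fru_c": 1}, 0, BIG, "transport", set()),
    ("CITt", "citrate uptake", {"cit_e": -1, "cit_c": 1}, 0, BIG, "transport", set()),
    ("MALt", "malate proton symport (uptake)",
     {"mal_e": -1, "h_e": -1, "mal_c": 1, "h_c": 1}, 0, BIG, "transport",
     {"proton_importer"}),
    ("CYSt", "cysteine uptake", {"cys_e": -1, "cys_c": 1}, 0, BIG, "transport", set()),
    ("THRt", "threonine uptake", {"thr_e": -1, "thr_c": 1}, 0, BIG, "transport", set()),
    ("VALt", "valine uptake", {"val_e": -1, "val_c": 1}, 0, BIG, "transport", set()),
    ("PHEt", "phenylalanine uptake", {"phe_e": -1, "phe_c": 1}, 0, BIG, "transport", set()),
    ("SERt", "serine uptake", {"ser_e": -1, "ser_c": 1}, 0, BIG, "transport", set()),
    ("MANt", "mannitol export", {"man_c": -1, "man_e": 1}, 0, BIG, "transport", set()),
    ("ERYt", "erythritol export", {"ery_c": -1, "ery_e": 1}, 0, BIG, "transport", set()),
    ("LLACt", "L-lactate proton symport",
     {"llac_c": -1, "h_c": -1, "llac_e": 1, "h_e": 1}, 0, BIG, "transport",
     {"proton_extruder"}),
    ("DLACt", "D-lactate proton symport",
     {"dlac_c": -1, "h_c": -1, "dlac_e": 1, "h_e": 1}, 0, BIG, "transport",
     {"proton_extruder"}),
    ("ACt", "acetate proton symport",
     {"ac_c": -1, "h_c": -1, "ac_e": 1, "h_e": 1}, 0, BIG, "transport",
     {"proton_extruder"}),
    ("ETOHt", "ethanol export", {"etoh_c": -1, "etoh_e": 1}, 0, BIG, "transport", set()),
    ("DIAt", "diacetyl export", {"dia_c": -1, "dia_e": 1}, 0, BIG, "transport", set()),
    ("CO2t", "CO2 export", {"co2_c": -1, "co2_e": 1}, 0, BIG, "transport", set()),
    ("NH3t", "ammonia export", {"nh3_c": -1, "nh3_e": 1}, 0, BIG, "transport", set()),
    ("H2St", "hydrogen sulfide export", {"h2s_c": -1, "h2s_e": 1}, 0, BIG, "transport", set()),
    ("O2t", "oxygen uptake", {"o2_e": -1, "o2_c": 1}, 0, BIG, "transport", set()),
    ("H2Ot", "water transport", {"h2o_e": -1, "h2o_c": 1}, -BIG, BIG, "transport", set()),
    ("PIt", "phosphate uptake", {"pi_e": -1, "pi_c": 1}, 0, BIG, "transport", set()),
    # -- sugar activation -------------------------------------------------
    ("HEX", "hexokinase",
     {"glc_c": -1, "atp_c": -1, "g6p_c": 1, "adp_c": 1, "h_c": 1},
     0, BIG, "glycolysis", set()),
    ("FRK", "fructokinase",
     {"fru_c": -1, "atp_c": -1, "f6p_c": 1, "adp_c": 1, "h_c": 1},
     0, BIG, "glycolysis", set()),
    ("PGI", "glucose-6P isomerase", {"g6p_c": -1, "f6p_c": 1}, -BIG, BIG,
     "glycolysis", set()),
    # -- oxidative branch + phosphoketolase backbone ----------------------
    ("G6PDH", "glucose-6P dehydrogenase",
     {"g6p_c": -1, "nadp_c": -1, "pg6_c": 1, "nadph_c": 1, "h_c": 1},
     0, BIG, "phosphoketolase", {"nadph_producer"}),
    ("PGDH", "phosphogluconate dehydrogenase",
     {"pg6_c": -1, "nadp_c": -1, "ru5p_c": 1, "co2_c": 1, "nadph_c": 1},
     0, BIG, "phosphoketolase", {"nadph_producer"}),
    ("RPE", "ribulose-5P 3-epimerase", {"ru5p_c": -1, "x5p_c": 1}, -BIG, BIG,
     "phosphoketolase", set()),
    ("XPK", "xylulose-5P phosphoketolase",
     {"x5p_c": -1, "pi_c": -1, "g3p_c": 1, "acp_c": 1, "h2o_c": 1},
     0, BIG, "phosphoketolase", set()),
    ("FPK", "fructose-6P phosphoketolase",
     {"f6p_c": -1, "pi_c": -1, "e4p_c": 1, "acp_c": 1, "h2o_c": 1},
     0, BIG, "phosphoketolase", set()),
    ("GAPD", "glyceraldehyde-3P dehydrogenase",
     {"g3p_c": -1, "nad_c": -1, "pi_c": -1, "bpg13_c": 1, "nadh_c": 1, "h_c": 1},
     -BIG, BIG, "phosphoketolase", {"nadh_producer"}),
    ("PGK", "3-phosphoglycerate kinase",
     {"bpg13_c": -1, "adp_c": -1, "pg3_c": 1, "atp_c": 1},
     -BIG, BIG, "phosphoketolase", {"atp_producer_pkp"}),
    ("PGM_ENO", "phosphoglycerate mutase + enolase",
     {"pg3_c": -1, "pep_c": 1, "h2o_c": 1}, -BIG, BIG, "phosphoketolase", set()),
    ("PYK", "pyruvate kinase",
     {"pep_c": -1, "adp_c": -1, "h_c": -1, "pyr_c": 1, "atp_c": 1},
     0, BIG, "phosphoketolase", {"atp_producer_pkp"}),
    ("DLDH", "D-lactate dehydrogenase",
     {"pyr_c": -1, "nadh_c": -1, "h_c": -1, "dlac_c": 1, "nad_c": 1},
     0, BIG, "phosphoketolase", set()),
    ("PTA", "phosphotransacetylase",
     {"acp_c": -1, "coa_c": -1, "accoa_c": 1, "pi_c": 1}, -BIG, BIG,
     "phosphoketolase", set()),
    ("ACK", "acetate kinase",
     {"acp_c": -1, "adp_c": -1, "ac_c": 1, "atp_c": 1},
     0, BIG, "phosphoketolase", {"atp_producer_pkp"}),
    ("ACALDH", "acetaldehyde dehydrogenase",
     {"accoa_c": -1, "nadh_c": -1, "h_c": -1, "acald_c": 1, "coa_c": 1, "nad_c": 1},
     0, BIG, "phosphoketolase", set()),
    ("ADH", "alcohol dehydrogenase",
     {"acald_c": -1, "nadh_c": -1, "h_c": -1, "etoh_c": 1, "nad_c": 1},
     0, BIG, "phosphoketolase", set()),
    # -- polyol formation -------------------------------------------------
    ("MANDH", "mannitol dehydrogenase (fructose reduction)",
     {"fru_c": -1, "nadh_c": -1, "h_c": -1, "man_c": 1, "nad_c": 1},
     0, BIG, "fructose_reduction", set()),
    ("ERYS", "erythrose-4P reduction + dephosphorylation",
     {"e4p_c": -1, "nadph_c": -1, "h_c": -1, "h2o_c": -1,
      "ery_c": 1, "nadp_c": 1, "pi_c": 1},
     0, BIG, "erythritol", set()),
    # -- malolactic fermentation and malate routes ------------------------
    ("MLF", "malolactic enzyme",
     {"mal_c": -1, "h_c": -1, "llac_c": 1, "co2_c": 1}, 0, BIG, "MLF", set()),
    ("MDH", "malate dehydrogenase",
     {"mal_c": -1, "nad_c": -1, "oaa_c": 1, "nadh_c": 1, "h_c": 1},
     0, BIG, "malic_enzyme", {"nadh_producer"}),
    # -- citrate degradation ----------------------------------------------
    ("CITL", "citrate lyase", {"cit_c": -1, "oaa_c": 1, "ac_c": 1},
     0, BIG, "citrate_degradation", set()),
    ("OAADC", "oxaloacetate decarboxylase",
     {"oaa_c": -1, "h_c": -1, "pyr_c": 1, "co2_c": 1},
     0, BIG, "citrate_degradation", set()),
    ("ALS", "acetolactate synthase",
     {"pyr_c": -2, "h_c": -1, "alac_c": 1, "co2_c": 1},
     0, BIG, "citrate_degradation", set()),
    ("DIAS", "acetolactate oxidative decarboxylation",
     {"alac_c": -1, "o2_c": -0.5, "dia_c": 1, "co2_c": 1, "h2o_c": 1},
     0, BIG, "citrate_degradation", set()),
    # -- amino acid degradation -------------------------------------------
    ("SERD", "serine deaminase", {"ser_c": -1, "pyr_c": 1, "nh3_c": 1},
     0, BIG, "aa_degradation", set()),
    ("CYSD", "cysteine desulfhydrase",
     {"cys_c": -1, "h2o_c": -1, "pyr_c": 1, "nh3_c": 1, "h2s_c": 1},
     0, BIG, "aa_degradation", set()),
    ("THRD", "threonine dehydrogenase (lumped to methylglyoxal)",
     {"thr_c": -1, "nad_c": -1, "mgx_c": 1, "co2_c": 1, "nh3_c": 1, "nadh_c": 1},
     0, BIG, "aa_degradation", {"nadh_producer"}),
    ("MGXD", "methylglyoxal degradation",
     {"mgx_c": -1, "nad_c": -1, "h2o_c": -1, "pyr_c": 1, "nadh_c": 1, "h_c": 1},
     0, BIG, "aa_degradation", {"nadh_producer"}),
    # -- redox housekeeping -----------------------------------------------
    ("THD", "NAD(P)+ transhydrogenase",
     {"nadph_c": -1, "nad_c": -1, "nadp_c": 1, "nadh_c": 1},
     0, BIG, "redox", {"nadh_producer"}),
    ("NQOR", "NADH quinone reductase (O2-terminated)",
     {"nadh_c": -1, "o2_c": -0.5, "h_c": -1, "nad_c": 1, "h2o_c": 1},
     0, BIG, "redox", set()),
    # -- energy -----------------------------------------------------------
    (ATPASE_ID, "F0F1-ATPase (synthesis direction)",
     {"adp_c": -1, "pi_c": -1, "h_e": -float(ATPASE_H_PER_ATP),
      "atp_c": 1, "h2o_c": 1, "h_c": float(ATPASE_H_PER_ATP) - 1},
     0, BIG, "ATPase", {"atp_producer_f0f1", "proton_importer"}),
    (NGAM_ID, "non-growth associated maintenance",
     {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1, "h_c": 1},
     0, BIG, "NGAM", set()),
    (BIOMASS_ID, "biomass formation", dict(BIOMASS_COMPOSITION),
     0, BIG, "biomass", set()),
]


def build_reduced_oeni_model() -> MetabolicNetwork:
    """Construct the reduced network programmatically (source of truth)."""
    mets = [Metabolite(i, n, c, f) for i, n, c, f in _M]
    rxns = [
        Reaction(i, {k: float(v) for k, v in st.items()},
                 float(lb), float(ub), sub, set(tags), name=n)
        for i, n, st, lb, ub, sub, tags in _R
    ]
    return MetabolicNetwork(
        mets, rxns, objective_id=BIOMASS_ID, name="reduced_oeni_central_carbon"
    )


def load_reduced_oeni_model() -> MetabolicNetwork:
    """Load the packaged reduced *O. oeni* central-carbon network.

    Reads the shipped JSON resource when present; falls back to the
    programmatic builder (both are kept identical by the test suite).
    """
    try:
        ref = resources.files("oenoflux.data").joinpath("reduced_oeni.json")
        data = json.loads(ref.read_text(encoding="utf-8"))
    except (FileNotFoundError, ModuleNotFoundError):
        return build_reduced_oeni_model()
    return _network_from_dict(data, source="packaged:reduced_oeni.json")
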