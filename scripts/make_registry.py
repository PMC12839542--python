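"""One-off generator for the shipped synthetic domain-signature registry.

Signatures are 60-aa blocks over the 19 non-tryptophan residues (decoy
proteins carry a periodic W lattice, so no decoy window can reach 90%
identity to any signature); pairwise 12-mer disjointness is enforced.
"""

import json
import pathlib

import numpy as np

ALPHA = "ACDEFGHIKLMNPQRSTVY"  # 19 residues, no W
SIG_LEN = 60
KMER = 12

DOMAINS = {
    # name: (family_class, description, extra)
    "AAA_ATPase": ("ATPase", "ORC/Cdc6-clade AAA+ ATPase module", {}),
    "MCM_ATPase": ("ATPase", "MCM-like AAA+ ATPase module of BrxL", {}),
    "iSTAND": ("sensor", "inactive STAND NTPase with eroded Walker motifs", {"walker_intact": False}),
    "STAND_walker": ("sensor", "STAND NTPase with intact Walker motifs", {"walker_intact": True}),
    "HerA_FtsK_translocase": ("translocase", "HerA/FtsK-superfamily DNA translocase", {}),
    "wHTH": ("HTH", "winged helix-turn-helix", {}),
    "HTH": ("HTH", "helix-turn-helix", {}),
    "SIGMA_HTH": ("HTH", "sigma-factor-like HTH of BrxL N-terminus", {}),
    "BrxA_HTH": ("HTH", "BrxA-family HTH unit", {}),
    "DUF4007_HTH": ("HTH", "DUF4007-family HTH unit", {}),
    "zinc_finger": ("HTH", "treble-clef zinc finger", {}),
    "alphabeta_core": ("other", "alpha/beta core insertion of BrxC/DUF499", {}),
    "coiledcoil": ("other", "coiled-coil extension", {}),
    "terminal_subdomain": ("other", "BrxC C-terminal subdomain", {}),
    "RRM": ("other", "RRM-like ferredoxin fold of DUF499", {}),
    "FnIII": ("other", "fibronectin-III-like beta sandwich", {}),
    "OB_fold": ("other", "OB-fold nucleic-acid-binding domain", {}),
    "TUDOR": ("sensor", "Tudor-like reader domain", {}),
    "HAS_barrel": ("other", "HAS beta-barrel of BrxHI", {}),
    "Lhr_CTD": ("other", "Lhr-type helicase C-terminal domain", {}),
    "alphabeta_CTD": ("other", "alpha/beta C-terminal domain of BrxHII", {}),
    "beta_sandwich": ("other", "PglZ C-terminal beta sandwich", {}),
    "helical_linker": ("other", "PglZ helical linker bundle", {}),
    "N_helical_bundle": ("other", "BrxX N-terminal helical bundle", {}),
    "coiledcoil_ext": ("other", "BrxX coiled-coil extension", {}),
    "DUF1156_helical": ("other", "DUF1156 N-terminal helical domain of BR MTases", {}),
    "DUF1795": ("other", "DUF1795-like domain of BrxP", {}),
    "ferredoxin_4Fe4S": ("other", "4Fe-4S ferredoxin domain of BrxP", {}),
    "ASCH_PUA": ("other", "ASCH/PUA-like RNA-binding domain", {}),
    "RAMA": ("other", "RAMA domain", {}),
    "DUF3780_core": ("other", "DUF3780 core domain", {}),
    "BrxE_signature": ("other", "BrxE family domain (Type-6 marker)", {}),
    "N6_MTase": ("MTase", "N6-adenine DNA methyltransferase catalytic fold", {}),
    "TRD_Cterm": ("MTase", "C-terminal target recognition domain (BrxX-type)", {}),
    "TRD_nested": ("MTase", "TRD nested within the MTase fold (BrxXI/BR-type)", {}),
    "PglZ_core": ("phosphatase", "alkaline-phosphatase-superfamily PglZ core", {}),
    "PAPS_reductase": ("modification", "phosphoadenylyl-sulfate reductase fold", {}),
    "cysteine_desulfurase": ("modification", "PLP-dependent cysteine desulfurase", {}),
    "GNAT_acetyltransferase": ("modification", "GNAT-fold acetyltransferase", {}),
    "TGT_core": ("modification", "tRNA-guanine transglycosylase fold", {}),
    "pseudokinase": ("modification", "PglW pseudokinase domain", {}),
    "STY_kinase": ("modification", "PglW active S/T/Y kinase domain", {}),
    "RNApolA_CTD": ("other", "RNA-polymerase-A-like CTD of PglW", {}),
    "Ski2_helicase": ("helicase", "Ski2-family helicase module of BrxHI", {}),
    "Swi2Snf2_helicase": ("helicase", "Swi2/Snf2-family helicase module", {}),
    "iSwi2Snf2": ("helicase", "inactive Swi2/Snf2 module of PglZ N-terminus", {}),
    # effector domains
    "PDDExK_REase": ("nuclease", "PD-(D/E)xK restriction endonuclease fold", {}),
    "NERD": ("nuclease", "NERD-family PD-(D/E)xK nuclease", {}),
    "Shedu_REase": ("nuclease", "Shedu-type PD-(D/E)xK nuclease", {}),
    "REase": ("nuclease", "restriction endonuclease domain fused to BR helicase", {}),
    "iREase": ("nuclease", "inactivated REase domain of BrxHII", {}),
    "HNH": ("nuclease", "HNH endonuclease", {}),
    "ParB_HNH": ("nuclease", "ParB-type HNH nuclease", {}),
    "SRA_HNH": ("nuclease", "SRA-associated HNH nuclease", {}),
    "HKD": ("nuclease", "HKD (phospholipase-D superfamily) endoDNase", {}),
    "TOPRIM": ("nuclease", "TOPRIM nuclease domain", {}),
    "OLD_ABC": ("nuclease", "OLD-family ABC ATPase nuclease partner", {}),
    "LonP": ("other", "LonP-like protease domain of BrxL", {}),
    "HEPN": ("nuclease", "HEPN endoRNase", {}),
    "MNT": ("modification", "minimal nucleotidyltransferase paired with HEPN", {}),
    "PIN": ("nuclease", "PIN endoRNase", {}),
    "Schlafen_kinase_wHTH": ("nuclease", "Schlafen-type kinase-wHTH abortive module", {}),
}


def main() -> None:
    rng = np.random.default_rng(20240917)
    sigs: dict[str, str] = {}
    seen_kmers: set[str] = set()
    for name in DOMAINS:
        while True:
            sig = "".join(rng.choice(list(ALPHA), size=SIG_LEN))
            kmers = {sig[i : i + KMER] for i in range(SIG_LEN - KMER + 1)}
            if not (kmers & seen_kmers):
                seen_kmers |= kmers
                sigs[name] = sig
                break
    entries = {
        name: {
            "signature": sigs[name],
            "family_class": fam,
            "description": desc,
            **extra,
        }
        for name, (fam, desc, extra) in DOMAINS.items()
    }
    out = {"registry_version": "1.0", "signature_length": SIG_LEN, "entries": entries}
    path = pathlib.Path(__file__).resolve().parents[1] / "src/brexmap/data/domain_registry.json"
    path.write_text(json.dumps(out, indent=1) + "\n")
    print(f"wrote {path} with {len(entries)} domains")


if __name__ == "__main__":
    main()
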