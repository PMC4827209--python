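# Default family-assignment rules.
#
# This file is DATA, not algorithm: it reconstructs the DBD-based family
# definitions compiled by the major plant/algal/cyanobacterial TF
# catalogues (PlantTFDB / PlnTFDB / cTFbase style). Pfam-style accessions
# are used where a standard signature exists; ALG_* accessions name the
# twelve custom DBD profiles (built from catalogue alignments) that the
# member databases do not cover. Replace this file to change the family
# universe; the classification engine only interprets the schema:
#
#   label      unique row name used in count tables
#   family     grouping name (subfamily rows of one family share it)
#   required   list of accession sets; every set must be hit, each with at
#              least min_copies non-overlapping instances (default 1)
#   forbidden  accessions that must NOT be hit
#   priority   integer, larger wins among matching rules (ties are invalid)
#   motif      curation-path rules assigned via a motif scan, not by the
#              generic engine (key into 'motifs')

motifs:
  # Recognition-helix signature of the SHAQKYF class of MYB-related TFs.
  shaqkyf: "SH[AL]QK[YF]"

myb_accessions: [PF00249]
g2like_accessions: [ALG_G2LIKE]

# Score (bit) cutoffs for the custom profiles, in the role of per-profile
# gathering thresholds for the hmmer evidence channel.
profile_thresholds:
  ALG_G2LIKE: 22.0
  ALG_BELL: 22.0
  ALG_HDZIP: 22.0
  ALG_HRT: 22.0
  ALG_NFYB: 22.0
  ALG_NFYC: 22.0
  ALG_SAP: 22.0
  ALG_STAT: 22.0
  ALG_TRIHELIX: 22.0
  ALG_VOZ: 22.0
  ALG_WOX: 22.0
  ALG_VARL: 22.0

families:
  # ---- multi-domain / copy-number rules (most specific first) ----
  - label: "DBB"
    required: [{accessions: [PF00643], min_copies: 2}]
    forbidden: [PF06203]
    priority: 1000
  - label: "C2C2-CO-like"
    superfamily: "C2C2"
    required:
      - {accessions: [PF00643]}
      - {accessions: [PF06203]}
    priority: 990
  - label: "GARP-ARR-B"
    superfamily: "GARP"
    required:
      - {accessions: [ALG_G2LIKE]}
      - {accessions: [PF00072]}
    priority: 980
  - label: "TALE"
    superfamily: "Homeobox"
    required:
      - {accessions: [PF00046]}
      - {accessions: [ALG_BELL]}
    priority: 970
  - label: "AP2"
    family: "AP2/ERF"
    subfamily: "AP2"
    superfamily: "AP2/ERF"
    required: [{accessions: [PF00847], min_copies: 2}]
    priority: 960
  - label: "NF-YB"
    superfamily: "NF-Y"
    required: [{accessions: [ALG_NFYB]}]
    forbidden: [ALG_NFYC]
    priority: 950
  - label: "NF-YC"
    superfamily: "NF-Y"
    required: [{accessions: [ALG_NFYC]}]
    forbidden: [ALG_NFYB]
    priority: 940
  - label: "NF-YA"
    superfamily: "NF-Y"
    required: [{accessions: [PF02045]}]
    priority: 930
  - label: "MYB (3R)"
    superfamily: "MYB"
    required: [{accessions: [PF00249], min_copies: 3}]
    priority: 920
  - label: "MYB (2R)"
    superfamily: "MYB"
    required: [{accessions: [PF00249], min_copies: 2}]
    priority: 910
  # Assigned by the MYB curation path (motif scan inside MYB repeats),
  # never by the generic engine.
  - label: "MYB-SHAQKYF"
    superfamily: "MYB"
    required: [{accessions: [PF00249]}]
    motif: shaqkyf
    priority: 905
  - label: "MYB-rel"
    superfamily: "MYB"
    required: [{accessions: [PF00249]}]
    priority: 890
  - label: "GARP-G2-like"
    superfamily: "GARP"
    required: [{accessions: [ALG_G2LIKE]}]
    forbidden: [PF00072]
    priority: 880
  - label: "ERF"
    family: "AP2/ERF"
    subfamily: "ERF"
    superfamily: "AP2/ERF"
    required: [{accessions: [PF00847]}]
    priority: 870

  # ---- single-DBD families ----
  - label: "ABI3/VP1"
    superfamily: "B3"
    required: [{accessions: [PF02362]}]
    priority: 860
  - label: "bHLH"
    required: [{accessions: [PF00010]}]
    priority: 850
  - label: "bZIP"
    required: [{accessions: [PF00170]}]
    priority: 840
  - label: "C2C2-Dof"
    superfamily: "C2C2"
    required: [{accessions: [PF02701]}]
    priority: 830
  - label: "C2C2-GATA"
    superfamily: "C2C2"
    required: [{accessions: [PF00320]}]
    priority: 820
  - label: "C2C2-LSD"
    superfamily: "C2C2"
    required: [{accessions: [PF06943]}]
    priority: 810
  - label: "C2H2"
    required: [{accessions: [PF00096]}]
    priority: 800
  - label: "C3H"
    required: [{accessions: [PF00642]}]
    priority: 790
  - label: "CCAAT"
    required: [{accessions: [PF00808]}]
    forbidden: [ALG_NFYB, ALG_NFYC]
    priority: 780
  - label: "CPP"
    required: [{accessions: [PF03638]}]
    priority: 770
  - label: "CSD"
    required: [{accessions: [PF00313]}]
    priority: 760
  - label: "E2F/DP"
    required: [{accessions: [PF02319]}]
    priority: 750
  - label: "Fungal TRF"
    required: [{accessions: [PF00172]}]
    priority: 740
  - label: "HB-other"
    superfamily: "Homeobox"
    required: [{accessions: [PF00046]}]
    forbidden: [ALG_BELL]
    priority: 730
  - label: "HSF"
    required: [{accessions: [PF00447]}]
    priority: 720
  - label: "LIM"
    required: [{accessions: [PF00412]}]
    priority: 710
  - label: "M-type"
    family: "M-type"
    superfamily: "MADS-box"
    required: [{accessions: [PF00319]}]
    priority: 700
  - label: "mTERF"
    required: [{accessions: [PF02536]}]
    priority: 690
  - label: "NF-X1"
    required: [{accessions: [PF01422]}]
    priority: 680
  - label: "Nin-like"
    required: [{accessions: [PF04937]}]
    priority: 670
  - label: "S1Fa-like"
    required: [{accessions: [PF04689]}]
    priority: 660
  - label: "SBP"
    required: [{accessions: [PF03110]}]
    priority: 650
  - label: "Sigma-70"
    required: [{accessions: [PF04542]}]
    priority: 640
  - label: "TUB"
    required: [{accessions: [PF01167]}]
    priority: 630
  - label: "VARL"
    required: [{accessions: [ALG_VARL]}]
    priority: 620
  - label: "Whirly"
    required: [{accessions: [PF08536]}]
    priority: 610
  - label: "WRKY"
    required: [{accessions: [PF03106]}]
    priority: 600

  # ---- cyanobacterial / bacterial-type families ----
  - label: "arsR"
    required: [{accessions: [PF01022]}]
    priority: 500
  - label: "Bac_DNA_binding"
    required: [{accessions: [PF00216]}]
    priority: 490
  - label: "BolA"
    required: [{accessions: [PF01722]}]
    priority: 480
  - label: "Crp"
    required: [{accessions: [PF00325]}]
    priority: 470
  - label: "FUR"
    required: [{accessions: [PF01475]}]
    priority: 460
  - label: "GerE"
    required: [{accessions: [PF00196]}]
    priority: 450
  - label: "GntR"
    required: [{accessions: [PF00392]}]
    priority: 440
  - label: "LysR"
    required: [{accessions: [PF00126]}]
    priority: 430
  - label: "SfsA"
    required: [{accessions: [PF03749]}]
    priority: 420
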