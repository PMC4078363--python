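# Default code configuration.
#
# ra_prefixes are the case-definition sets under study and should normally
# not be edited. other_rheum_prefixes are IMPLEMENTER-SUPPLIED defaults for
# the named exclusion conditions (osteoarthritis, gout, polymyalgia
# rheumatica, spondyloarthropathy/ankylosing spondylitis, connective tissue
# disorder, psoriasis, synovitis/tenosynovitis/bursitis, vasculitis) — no
# official code list accompanies the definitions, so override freely.
# Matching is prefix-based, case- and dot-insensitive.

ra_prefixes:
  OHIP_DX: ["714"]
  ICD9: ["714"]
  ICD10: ["M05", "M06"]

other_rheum_prefixes:
  OHIP_DX: ["715", "274", "725", "720", "710", "696", "727", "446", "447"]
  ICD9: ["715", "274", "725", "720", "710", "696", "727", "446", "447"]
  ICD10:
    ["M15", "M16", "M17", "M18", "M19",   # osteoarthritis
     "M10",                               # gout
     "M353",                              # polymyalgia rheumatica
     "M45", "M46",                        # ankylosing spondylitis / spondylopathies
     "M30", "M31", "M32", "M33", "M34", "M35",  # connective tissue / vasculitis
     "L40",                               # psoriasis
     "M65", "M70", "M71"]                 # synovitis / tenosynovitis / bursitis

msk_specialties:
  - rheumatology
  - orthopedic surgery
  - internal medicine

drug_class_map:
  methotrexate: DMARD
  hydroxychloroquine: DMARD
  sulfasalazine: DMARD
  leflunomide: DMARD
  etanercept: BIOLOGIC
  infliximab: BIOLOGIC
  adalimumab: BIOLOGIC
  prednisone: GLUCOCORTICOSTEROID
  methylprednisolone: GLUCOCORTICOSTEROID
  naproxen: NSAID_COXIB
  celecoxib: NSAID_COXIB
  ibuprofen: NSAID_COXIB
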