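{
  "_comment": "Editable curated genus lists for the selection screen. known_pgpb_genera: genera previously reported as sugar-beet growth promoters. pathogen_genera: plant/animal/human pathogen genera excluded from candidacy.",
  "known_pgpb_genera": [
    "Acinetobacter",
    "Bacillus",
    "Burkholderia",
    "Chryseobacterium",
    "Paenibacillus",
    "Pseudomonas",
    "Rhodobacter",
    "Stenotrophomonas"
  ],
  "pathogen_genera": [
    "Agrobacterium",
    "Brucella",
    "Clavibacter",
    "Dickeya",
    "Erwinia",
    "Klebsiella",
    "Legionella",
    "Listeria",
    "Pectobacterium",
    "Ralstonia",
    "Salmonella",
    "Shigella",
    "Staphylococcus",
    "Xanthomonas",
    "Xylella"
  ]
}
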