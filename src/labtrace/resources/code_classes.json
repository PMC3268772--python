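{
  "BREED": "breeds of animals or varieties of plants",
  "COUNTRY": "countries of users or contacts",
  "LANGUAGE": "speaking languages of users or contacts",
  "MARKER_TYPE": "types of molecular markers",
  "MATERIAL_TYPE": "types of biological materials",
  "METHOD": "electrophoresis methods for sequencing",
  "MIMETYPE": "types of file extension",
  "PRIMER": "names of PCR primers",
  "PROTOCOL_TYPE": "types of experimental protocols",
  "PURPOSE": "sequencing or genotyping",
  "SEX": "genders of individuals",
  "SOFTWARE": "software tools used to analyze data",
  "SPECIES": "species of individuals",
  "VESSEL_TYPE": "types of vessels for storing samples"
}
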