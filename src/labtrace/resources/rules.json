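{
  "codes": {
    "not_null": ["code_class", "short_name"],
    "unique": [["code_class", "short_name"]],
    "foreign_key": {},
    "type": {"active": "bool"},
    "non_empty": ["short_name"]
  },
  "unit": {
    "not_null": ["name"],
    "unique": [["name"]],
    "foreign_key": {},
    "type": {},
    "non_empty": ["name"]
  },
  "contacts": {
    "not_null": ["name"],
    "unique": [],
    "foreign_key": {
      "unit_id": {"relation": "unit", "column": "unit_id"},
      "country_id": {"class": "COUNTRY"},
      "language_id": {"class": "LANGUAGE"}
    },
    "type": {},
    "non_empty": ["name"]
  },
  "blobs": {
    "not_null": ["content", "checksum", "checksum_algo", "size"],
    "unique": [],
    "foreign_key": {"mimetype_id": {"class": "MIMETYPE"}},
    "type": {"size": "int", "content": "blob"},
    "non_negative": ["size"]
  },
  "protocols": {
    "not_null": ["name"],
    "unique": [["name", "protocol_type_id"]],
    "foreign_key": {
      "protocol_type_id": {"class": "PROTOCOL_TYPE"},
      "blob_id": {"relation": "blobs", "column": "blob_id"}
    },
    "type": {},
    "non_empty": ["name"]
  },
  "projects": {
    "not_null": ["name", "purpose_id"],
    "unique": [["name"]],
    "foreign_key": {
      "purpose_id": {"class": "PURPOSE"},
      "owner_contact_id": {"relation": "contacts", "column": "contact_id"}
    },
    "type": {"start_date": "date"},
    "non_empty": ["name"]
  },
  "organisms": {
    "not_null": ["species_id"],
    "unique": [],
    "foreign_key": {
      "species_id": {"class": "SPECIES"},
      "breed_id": {"class": "BREED"},
      "sex_id": {"class": "SEX"}
    },
    "type": {"birth_date": "date"}
  },
  "transfer": {
    "not_null": ["organism_id", "external_id", "id_system"],
    "unique": [["id_system", "external_id"]],
    "foreign_key": {"organism_id": {"relation": "organisms", "column": "organism_id"}},
    "type": {},
    "non_empty": ["external_id", "id_system"]
  },
  "storage": {
    "not_null": ["storage_name"],
    "unique": [["storage_name", "parent_id"]],
    "foreign_key": {"parent_id": {"relation": "storage", "column": "storage_id"}},
    "type": {},
    "non_empty": ["storage_name"]
  },
  "samples": {
    "not_null": ["organism_id", "project_id", "material_type_id"],
    "unique": [],
    "foreign_key": {
      "organism_id": {"relation": "organisms", "column": "organism_id"},
      "project_id": {"relation": "projects", "column": "project_id"},
      "material_type_id": {"class": "MATERIAL_TYPE"},
      "vessel_type_id": {"class": "VESSEL_TYPE"}
    },
    "type": {"amount": "num"},
    "non_negative": ["amount"]
  },
  "storage_samples": {
    "not_null": ["item_type", "item_id", "storage_id", "date_in"],
    "unique": [],
    "foreign_key": {"storage_id": {"relation": "storage", "column": "storage_id"}},
    "type": {"date_in": "date", "date_out": "date", "item_id": "int"},
    "enum": {"item_type": ["sample", "dna"]}
  },
  "sample_collection": {
    "not_null": ["sample_id"],
    "unique": [],
    "foreign_key": {
      "sample_id": {"relation": "samples", "column": "sample_id"},
      "contact_id": {"relation": "contacts", "column": "contact_id"}
    },
    "type": {"date": "date"}
  },
  "dna_extraction": {
    "not_null": ["dna_id", "sample_id"],
    "unique": [["dna_id", "sample_id"]],
    "foreign_key": {
      "sample_id": {"relation": "samples", "column": "sample_id"},
      "protocol_id": {"relation": "protocols", "column": "protocol_id"},
      "contact_id": {"relation": "contacts", "column": "contact_id"}
    },
    "type": {"dna_id": "int", "date": "date", "concentration": "num"},
    "non_negative": ["concentration"]
  },
  "pcr_amplification": {
    "not_null": [],
    "unique": [],
    "foreign_key": {"protocol_id": {"relation": "protocols", "column": "protocol_id"}},
    "type": {"date": "date"}
  },
  "pcr_markers": {
    "not_null": ["pcr_id", "primer_id"],
    "unique": [["pcr_id", "primer_id"]],
    "foreign_key": {
      "pcr_id": {"relation": "pcr_amplification", "column": "pcr_id"},
      "primer_id": {"class": "PRIMER"},
      "marker_type_id": {"class": "MARKER_TYPE"}
    },
    "type": {}
  },
  "amplified_samples": {
    "not_null": ["pcr_id", "dna_id"],
    "unique": [["pcr_id", "dna_id"]],
    "foreign_key": {
      "pcr_id": {"relation": "pcr_amplification", "column": "pcr_id"},
      "dna_id": {"relation": "dna_extraction", "column": "dna_id"}
    },
    "type": {"dna_id": "int"}
  },
  "electrophoresis": {
    "not_null": ["pcr_id"],
    "unique": [],
    "foreign_key": {
      "pcr_id": {"relation": "pcr_amplification", "column": "pcr_id"},
      "method_id": {"class": "METHOD"}
    },
    "type": {"date": "date"}
  },
  "validation": {
    "not_null": ["target_type", "target_id", "result"],
    "unique": [],
    "foreign_key": {},
    "type": {"target_id": "int"},
    "enum": {"target_type": ["dna", "pcr"], "result": ["pass", "fail", "ambiguous"]}
  },
  "gel_images": {
    "not_null": ["validation_id", "blob_id"],
    "unique": [],
    "foreign_key": {
      "validation_id": {"relation": "validation", "column": "validation_id"},
      "blob_id": {"relation": "blobs", "column": "blob_id"}
    },
    "type": {}
  },
  "sequences": {
    "not_null": ["pcr_id", "dna_id", "primer_id", "bases"],
    "unique": [],
    "foreign_key": {
      "pcr_id": {"relation": "pcr_amplification", "column": "pcr_id"},
      "dna_id": {"relation": "dna_extraction", "column": "dna_id"},
      "primer_id": {"class": "PRIMER"},
      "software_id": {"class": "SOFTWARE"}
    },
    "type": {"dna_id": "int", "length": "int"},
    "iupac": ["bases"],
    "non_empty": ["bases"]
  },
  "microsatellites": {
    "not_null": ["dna_id", "primer_id"],
    "unique": [["dna_id", "primer_id"]],
    "foreign_key": {
      "dna_id": {"relation": "dna_extraction", "column": "dna_id"},
      "primer_id": {"class": "PRIMER"},
      "software_id": {"class": "SOFTWARE"}
    },
    "type": {"dna_id": "int", "allele1": "int", "allele2": "int"},
    "positive": ["allele1", "allele2"]
  },
  "users": {
    "not_null": ["login", "pw_hash", "salt", "system_role", "db_role"],
    "unique": [["login"]],
    "foreign_key": {
      "contact_id": {"relation": "contacts", "column": "contact_id"},
      "system_role": {"relation": "user_roles", "column": "role_name"},
      "db_role": {"relation": "user_roles", "column": "role_name"}
    },
    "type": {"active": "bool"},
    "non_empty": ["login"]
  },
  "user_roles": {
    "not_null": ["role_type", "role_name"],
    "unique": [["role_type", "role_name"]],
    "foreign_key": {},
    "type": {},
    "enum": {"role_type": ["system", "database"]}
  }
}
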