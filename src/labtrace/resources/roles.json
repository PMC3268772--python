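{
  "system_tasks": {
    "a": "manage user accounts",
    "b": "enter and modify own workflow data",
    "c": "search and view data",
    "d": "generate reports",
    "e": "export data",
    "f": "manage lab-wide resources (codes, protocols, storage, any project's data)",
    "g": "manage own account and password"
  },
  "system_roles": {
    "user_administrator": ["a", "g"],
    "lab_manager": ["c", "d", "e", "f", "g"],
    "scientist": ["b", "c", "d", "e", "g"],
    "visitor": ["c", "d", "g"]
  },
  "data_actions": ["read", "write", "delete", "manage_user"],
  "db_roles": {
    "read": ["read"],
    "write": ["read", "write"],
    "delete": ["delete"],
    "manage_user": ["manage_user"],
    "full_right": ["read", "write", "delete", "manage_user"]
  }
}
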