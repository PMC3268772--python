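"""Dual-role access control.

Each account carries exactly one system role (which functional areas of the
application are visible: four roles over seven tasks a-g) and one database
role (which data manipulations are permitted: five roles over four data
actions).  Both matrices are data, loaded from a plain-text JSON file, so
authorization outcomes can be changed without touching code.
"""

from __future__ import annotations

import hashlib
import json
import os
import secrets
from dataclasses import dataclass
from importlib import resources as _ilres

from .errors import AuthenticationError, NotFoundError, PermissionDeniedError

_PBKDF2_ITERATIONS = 20_000  # modest: demo datasets create many accounts


@dataclass(frozen=True)
class Session:
    """An authenticated principal bound to its two roles."""
    user_id: int | None
    login: str
    system_role: str
    db_role: str


class AccessPolicy:
    """The two role matrices plus the closed task/action vocabularies."""

    def __init__(self, config: dict):
        self.system_tasks: dict[str, str] = dict(config["system_tasks"])
        self.system_roles: dict[str, list[str]] = {
            r: list(ts) for r, ts in config["system_roles"].items()}
        self.data_actions: list[str] = list(config["data_actions"])
        self.db_roles: dict[str, list[str]] = {
            r: list(a) for r, a in config["db_roles"].items()}
        for role, tasks in self.system_roles.items():
            for t in tasks:
                if t not in self.system_tasks:
                    raise NotFoundError(f"system role {role}: unknown task {t!r}")
        for role, actions in self.db_roles.items():
            for a in actions:
                if a not in self.data_actions:
                    raise NotFoundError(f"db role {role}: unknown action {a!r}")

    @classmethod
    def default(cls) -> "AccessPolicy":
        with _ilres.files("labtrace.resources").joinpath("roles.json").open(
                "r", encoding="utf-8") as fh:
            return cls(json.load(fh))

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "AccessPolicy":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(json.load(fh))

    def allows_system(self, session: Session, task: str) -> bool:
        if task not in self.system_tasks:
            raise NotFoundError(f"unknown system task {task!r}")
        return task in self.system_roles.get(session.system_role, ())

    def allows_data(self, session: Session, action: str) -> bool:
        if session is SYSTEM_SESSION:
            return True
        if action not in self.data_actions:
            raise NotFoundError(f"unknown data action {action!r}")
        return action in self.db_roles.get(session.db_role, ())


#: Implicit superuser session used when no login has taken place (library
#: embedding, CLI on a local file).  Never persisted.
SYSTEM_SESSION = Session(None, "__system__", "lab_manager", "full_right")


def _digest(secret: str, salt: str) -> str:
    return hashlib.pbkdf2_hmac(
        "sha256", secret.encode(), bytes.fromhex(salt), _PBKDF2_ITERATIONS).hex()


def create_user(db, login: str, secret: str, *, system_role: str,
                db_role: str, contact_id: int | None = None,
                salt: str | None = None) -> int:
    """Create an account with a salted credential digest (never plaintext).

    ``salt`` is normally generated; passing one explicitly exists for
    deterministic dataset generation only.
    """
    if system_role not in db.policy.system_roles:
        raise NotFoundError(f"unknown system role {system_role!r}")
    if db_role not in db.policy.db_roles:
        raise NotFoundError(f"unknown database role {db_role!r}")
    salt = salt or secrets.token_hex(16)
    return db.insert("users", {
        "login": login, "salt": salt, "pw_hash": _digest(secret, salt),
        "contact_id": contact_id, "system_role": system_role,
        "db_role": db_role, "active": 1})


def set_active(db, login: str, active: bool) -> None:
    row = db.one("SELECT user_id FROM users WHERE login=?", (login,))
    if row is None:
        raise NotFoundError(f"no user {login!r}")
    db.update("users", row["user_id"], {"active": 1 if active else 0})


def authenticate(db, login: str, secret: str) -> Session:
    """Verify credentials; all failure modes raise the same opaque error."""
    row = db.one("SELECT * FROM users WHERE login=?", (login,))
    ok = (row is not None
          and bool(row["active"])
          and secrets.compare_digest(row["pw_hash"], _digest(secret, row["salt"])))
    if not ok:
        raise AuthenticationError("invalid credentials")
    return Session(row["user_id"], row["login"], row["system_role"], row["db_role"])


def authorize(db, session: Session, action: str, *, kind: str = "data") -> bool:
    """Check one action against the appropriate matrix; deny wins."""
    if kind == "system":
        return db.policy.allows_system(session, action)
    if kind == "data":
        return db.policy.allows_data(session, action)
    raise NotFoundError(f"unknown authorization kind {kind!r}")


def require(db, session: Session, action: str, *, kind: str = "data") -> None:
    if not authorize(db, session, action, kind=kind):
        raise PermissionDeniedError(f"{session.login!r} may not {action} ({kind})")
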