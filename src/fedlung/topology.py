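"""Client → routing-server → central-server hierarchy and data partitioning.

The federation is simulated in-process: nodes are opaque integer ids, the
central server a singleton. Training cases are sharded across clients
either IID (stratified round-robin after a seeded shuffle) or with label
skew drawn from a symmetric Dirichlet.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .cohort import CLASS_LABELS


@dataclass(frozen=True)
class ClientNode:
    client_id: int
    router_id: int
    shard: tuple[str, ...] = ()


@dataclass(frozen=True)
class RouterNode:
    router_id: int
    client_ids: frozenset[int]


@dataclass(frozen=True)
class Topology:
    clients: tuple[ClientNode, ...]
    routers: tuple[RouterNode, ...]
    central_id: str = "SX"

    def __post_init__(self) -> None:
        seen: dict[int, int] = {}
        for r in self.routers:
            if not r.client_ids:
                raise ValueError(f"router {r.router_id} has no clients")
            for c in r.client_ids:
                if c in seen:
                    raise ValueError(f"client {c} assigned to two routers")
                seen[c] = r.router_id
        for c in self.clients:
            if seen.get(c.client_id) != c.router_id:
                raise ValueError(f"client {c.client_id} router link inconsistent")
        if len(seen) != len(self.clients):
            raise ValueError("router client sets do not cover the clients")

    @property
    def n_clients(self) -> int:
        return len(self.clients)

    def client(self, client_id: int) -> ClientNode:
        return self.clients[client_id]

    def shards(self) -> dict[int, tuple[str, ...]]:
        return {c.client_id: c.shard for c in self.clients}


def default_router_count(n_clients: int) -> int:
    """ceil(sqrt(n)) routing servers for n clients."""
    return int(math.ceil(math.sqrt(n_clients)))


def build_topology(n_clients: int, n_routers: int | None = None) -> Topology:
    """Round-robin client→router assignment; router k gets {i : i mod R = k}."""
    if n_clients < 1:
        raise ValueError("need at least one client")
    if n_routers is None:
        n_routers = default_router_count(n_clients)
    if not (1 <= n_routers <= n_clients):
        raise ValueError("need 1 <= n_routers <= n_clients")
    clients = tuple(
        ClientNode(client_id=i, router_id=i % n_routers) for i in range(n_clients)
    )
    routers = tuple(
        RouterNode(
            router_id=k,
            client_ids=frozenset(i for i in range(n_clients) if i % n_routers == k),
        )
        for k in range(n_routers)
    )
    return Topology(clients=clients, routers=routers)


def _largest_remainder(total: int, props: np.ndarray) -> np.ndarray:
    raw = total * props / props.sum()
    counts = np.floor(raw).astype(int)
    frac = raw - counts
    order = np.argsort(-frac, kind="stable")
    for i in range(total - counts.sum()):
        counts[order[i]] += 1
    return counts


def partition(
    train_cases: Sequence[tuple[str, str]],
    topology: Topology,
    scheme: str = "iid",
    skew_alpha: float = 0.5,
    seed: int = 0,
) -> Topology:
    """Fill client shards with case ids; returns a new Topology.

    ``train_cases`` is a sequence of (case_id, label). IID deals cases
    round-robin per class after a seeded shuffle; label_skew splits each
    class across clients by proportions drawn from Dirichlet(skew_alpha).
    The result is always a set partition of the input.
    """
    if scheme not in ("iid", "label_skew"):
        raise ValueError(f"unknown partition scheme {scheme!r}")
    n_clients = topology.n_clients
    if len(train_cases) < n_clients:
        raise ValueError("fewer training cases than clients")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xA4)))
    shards: list[list[str]] = [[] for _ in range(n_clients)]
    by_class: dict[str, list[str]] = {lab: [] for lab in CLASS_LABELS}
    for cid, lab in train_cases:
        by_class[lab].append(cid)

    if scheme == "iid":
        offset = 0
        for lab in CLASS_LABELS:
            ids = list(by_class[lab])
            perm = rng.permutation(len(ids))
            for j, p in enumerate(perm):
                shards[(offset + j) % n_clients].append(ids[p])
            offset += len(ids)
    else:
        for lab in CLASS_LABELS:
            ids = list(by_class[lab])
            if not ids:
                continue
            perm = rng.permutation(len(ids))
            props = rng.dirichlet(np.full(n_clients, skew_alpha))
            counts = _largest_remainder(len(ids), props)
            pos = 0
            for client, c in enumerate(counts):
                for j in range(c):
                    shards[client].append(ids[perm[pos]])
                    pos += 1

    # re-balance: an empty shard takes one case from the largest shard
    for client in range(n_clients):
        while not shards[client]:
            donor = max(range(n_clients), key=lambda i: len(shards[i]))
            if len(shards[donor]) <= 1:
                raise ValueError("cannot fill every shard with at least one case")
            shards[client].append(shards[donor].pop())

    clients = tuple(
        replace(c, shard=tuple(shards[c.client_id])) for c in topology.clients
    )
    return Topology(clients=clients, routers=topology.routers)


def to_json(topology: Topology) -> str:
    return json.dumps(
        {
            "routers": [
                {"router_id": r.router_id, "client_ids": sorted(r.client_ids)}
                for r in topology.routers
            ],
            "clients": [
                {
                    "client_id": c.client_id,
                    "router_id": c.router_id,
                    "case_ids": list(c.shard),
                }
                for c in topology.clients
            ],
        },
        indent=2,
    )


def from_json(text: str) -> Topology:
    d = json.loads(text)
    clients = tuple(
        ClientNode(
            client_id=c["client_id"],
            router_id=c["router_id"],
            shard=tuple(c["case_ids"]),
        )
        for c in d["clients"]
    )
    routers = tuple(
        RouterNode(router_id=r["router_id"], client_ids=frozenset(r["client_ids"]))
        for r in d["routers"]
    )
    return Topology(clients=clients, routers=routers)


def save_topology(topology: Topology, path: str | Path) -> None:
    Path(path).write_text(to_json(topology))


def load_topology(path: str | Path) -> Topology:
    return from_json(Path(path).read_text())
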