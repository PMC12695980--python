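"""Party communication: in-process queues or TCP sockets, with transcript hooks.

Every session has exactly one server role and P node roles.  All messages
traverse the server's transcript hook, which records direction, stage label,
payload kind and shape (and optionally a digest of every payload row) so the
privacy assertions can audit exactly what the server was able to observe.

Serialization (TCP backend): little-endian framing —
8-byte magic+version, 4-byte header length, JSON header (stage, kind, dtype,
shape), raw row-major array bytes.  Doubles round-trip bit-exactly, so the
two backends produce identical results.
"""

from __future__ import annotations

import hashlib
import json
import queue
import socket
import struct
import threading
from dataclasses import dataclass, field

import numpy as np

MAGIC = b"FGWAS\x00\x01\x00"

SERVER = "server"


@dataclass
class Envelope:
    sender: str
    recipient: str
    stage: str
    kind: str
    payload: np.ndarray


@dataclass
class TranscriptRecord:
    direction: str      # "node->server" or "server->node"
    party: str
    stage: str
    kind: str
    shape: tuple
    row_digests: frozenset | None = None


@dataclass
class ServerTranscript:
    """Ordered log of everything the server sent or received."""

    records: list = field(default_factory=list)
    audit_rows: bool = True

    def log(self, direction: str, env: Envelope) -> None:
        payload = np.asarray(env.payload)
        digests = None
        if self.audit_rows:
            digests = frozenset(_row_digests(payload))
        self.records.append(
            TranscriptRecord(
                direction=direction,
                party=env.sender if direction == "node->server" else env.recipient,
                stage=env.stage,
                kind=env.kind,
                shape=tuple(payload.shape),
                row_digests=digests,
            )
        )

    def kinds(self) -> set:
        return {r.kind for r in self.records}

    def shapes(self) -> list:
        return [r.shape for r in self.records]

    def all_row_digests(self) -> set:
        out: set = set()
        for r in self.records:
            if r.row_digests:
                out |= r.row_digests
        return out


def _row_digests(payload: np.ndarray):
    arr = np.atleast_2d(np.asarray(payload, dtype=np.float64))
    for row in arr:
        yield hashlib.sha1(np.ascontiguousarray(row).tobytes()).digest()


def row_digest(row: np.ndarray) -> bytes:
    """Digest of one canonical float64 row; used by the privacy audit."""
    return hashlib.sha1(np.ascontiguousarray(np.asarray(row, dtype=np.float64)).tobytes()).digest()


class Endpoint:
    """One party's view of the session; send/receive are per-peer FIFO."""

    def __init__(self, party_id: str):
        self.party_id = party_id

    def send(self, recipient: str, stage: str, kind: str, payload) -> None:
        raise NotImplementedError

    def receive(self, sender: str) -> Envelope:
        raise NotImplementedError


class InProcessEndpoint(Endpoint):
    def __init__(self, party_id: str, queues: dict, transcript: ServerTranscript):
        super().__init__(party_id)
        self._queues = queues
        self._transcript = transcript
        self._lock = threading.Lock()

    def send(self, recipient: str, stage: str, kind: str, payload) -> None:
        env = Envelope(self.party_id, recipient, stage, kind, np.asarray(payload))
        if recipient == SERVER:
            with self._lock:
                self._transcript.log("node->server", env)
        elif self.party_id == SERVER:
            with self._lock:
                self._transcript.log("server->node", env)
        self._queues[(self.party_id, recipient)].put(env)

    def receive(self, sender: str) -> Envelope:
        env = self._queues[(sender, self.party_id)].get(timeout=600)
        if isinstance(env, Exception):
            raise RuntimeError(f"peer {sender} aborted") from env
        return env


def _pack(env: Envelope) -> bytes:
    arr = np.ascontiguousarray(np.asarray(env.payload))
    if arr.dtype not in (np.float64, np.int64):
        arr = arr.astype(np.float64)
    header = json.dumps(
        {
            "sender": env.sender,
            "recipient": env.recipient,
            "stage": env.stage,
            "kind": env.kind,
            "dtype": arr.dtype.str,
            "shape": list(arr.shape),
        }
    ).encode()
    body = arr.tobytes(order="C")
    checksum = hashlib.sha1(body).digest()[:8]
    return MAGIC + struct.pack("<I", len(header)) + header + struct.pack("<Q", len(body)) + checksum + body


def _recv_exact(sock: socket.socket, n: int) -> bytes:
    chunks = []
    while n:
        chunk = sock.recv(min(n, 1 << 20))
        if not chunk:
            raise ConnectionError("peer closed mid-frame")
        chunks.append(chunk)
        n -= len(chunk)
    return b"".join(chunks)


def _unpack(sock: socket.socket) -> Envelope:
    magic = _recv_exact(sock, len(MAGIC))
    if magic != MAGIC:
        raise ValueError("bad frame magic")
    (hlen,) = struct.unpack("<I", _recv_exact(sock, 4))
    header = json.loads(_recv_exact(sock, hlen))
    (blen,) = struct.unpack("<Q", _recv_exact(sock, 8))
    checksum = _recv_exact(sock, 8)
    body = _recv_exact(sock, blen)
    if hashlib.sha1(body).digest()[:8] != checksum:
        raise ValueError("frame checksum mismatch")
    arr = np.frombuffer(body, dtype=np.dtype(header["dtype"])).reshape(header["shape"]).copy()
    return Envelope(header["sender"], header["recipient"], header["stage"], header["kind"], arr)


class TcpEndpoint(Endpoint):
    """Hub-and-spoke TCP: every party talks to the server's port fan-in.

    Node-to-node traffic is not part of the protocol, so each node keeps one
    socket to the server; the server keeps one per node.
    """

    def __init__(self, party_id: str, socks: dict, transcript: ServerTranscript | None):
        super().__init__(party_id)
        self._socks = socks
        self._transcript = transcript
        self._lock = threading.Lock()

    def send(self, recipient: str, stage: str, kind: str, payload) -> None:
        env = Envelope(self.party_id, recipient, stage, kind, np.asarray(payload))
        if self._transcript is not None:
            direction = "server->node" if self.party_id == SERVER else "node->server"
            with self._lock:
                self._transcript.log(direction, env)
        self._socks[recipient].sendall(_pack(env))

    def receive(self, sender: str) -> Envelope:
        env = _unpack(self._socks[sender])
        if env.sender != sender:
            raise ValueError("message from unexpected sender on channel")
        return env


def make_inprocess_session(n_nodes: int, audit_rows: bool = True):
    """Endpoints for one server + n nodes, sharing a transcript."""
    transcript = ServerTranscript(audit_rows=audit_rows)
    parties = [SERVER] + [f"node{p}" for p in range(n_nodes)]
    queues = {(a, b): queue.Queue() for a in parties for b in parties if a != b}
    endpoints = {pid: InProcessEndpoint(pid, queues, transcript) for pid in parties}
    return endpoints, transcript


def run_session(party_programs: dict, endpoints: dict):
    """Run each party's program in its own thread; abort cleanly on failure.

    party_programs maps party id -> callable(endpoint) -> result.  Returns
    {party id: result}.  Any party exception aborts the session with the
    failing stage in the error.
    """
    results: dict = {}
    errors: dict = {}

    def runner(pid, program):
        try:
            results[pid] = program(endpoints[pid])
        except Exception as exc:  # propagate with party label
            errors[pid] = exc
            # unblock any peer waiting on us
            ep = endpoints[pid]
            if isinstance(ep, InProcessEndpoint):
                for (a, b), q in ep._queues.items():
                    if a == pid:
                        q.put(exc)

    threads = [threading.Thread(target=runner, args=(pid, prog), daemon=True) for pid, prog in party_programs.items()]
    for t in threads:
        t.start()
    for t in threads:
        t.join()
    if errors:
        pid, exc = sorted(errors.items())[0]
        raise RuntimeError(f"session aborted: party {pid} failed: {exc}") from exc
    return results


def serve_tcp(host: str, port: int, n_nodes: int, audit_rows: bool = True):
    """Server side of a TCP session: accept one connection per node."""
    transcript = ServerTranscript(audit_rows=audit_rows)
    listener = socket.create_server((host, port))
    socks = {}
    for _ in range(n_nodes):
        conn, _addr = listener.accept()
        hello = _unpack(conn)
        if hello.kind != "hello":
            raise ValueError("expected hello frame")
        socks[hello.sender] = conn
    listener.close()
    return TcpEndpoint(SERVER, socks, transcript), transcript


def connect_tcp(host: str, port: int, party_id: str, retry_seconds: float = 30.0):
    """Node side of a TCP session; retries until the server is listening."""
    import time

    deadline = time.monotonic() + retry_seconds
    while True:
        try:
            sock = socket.create_connection((host, port), timeout=600)
            break
        except OSError:
            if time.monotonic() >= deadline:
                raise
            time.sleep(0.1)
    ep = TcpEndpoint(party_id, {SERVER: sock}, None)
    sock.sendall(_pack(Envelope(party_id, SERVER, "setup", "hello", np.zeros(0))))
    return ep
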