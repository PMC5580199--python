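"""Hybrid record envelopes: AES-128 transport, RSA key wrapping, AES-256
at rest.

Transport: each envelope gets a fresh random 128-bit AES key; the payload is
encrypted with AES-CTR and authenticated with an HMAC-SHA256 tag
(encrypt-then-MAC, both subkeys derived from the envelope key), and the AES
key is wrapped with the recipient's RSA public key under OAEP.  A SHA-256
digest of the plaintext rides along for end-to-end integrity verification.
Any tampering or key mismatch fails loudly — never silent corruption.

At rest: stored blobs use 256-bit AES in cipher-block-chaining mode, with
the plaintext digest sealed inside the ciphertext so modification is
detected on decryption.

Keys live in an in-memory registry keyed by opaque ``key_id`` strings; there
is no HSM and no network key exchange.
"""

from __future__ import annotations

import base64
import hashlib
import hmac
import json
import secrets
from dataclasses import dataclass

from ._aes import AES, pkcs7_pad, pkcs7_unpad
from ._rsa import (
    DecryptionError,
    RSAPrivateKey,
    RSAPublicKey,
    generate_keypair,
    oaep_decrypt,
    oaep_encrypt,
)

__all__ = [
    "TRANSPORT_KEY_BYTES",
    "STORAGE_KEY_BYTES",
    "EnvelopeError",
    "IntegrityError",
    "DecryptionError",
    "Envelope",
    "KeyRegistry",
    "seal",
    "open_envelope",
    "reencrypt_at_rest",
    "decrypt_at_rest",
]

#: Transport symmetric key: exactly 128 bits.
TRANSPORT_KEY_BYTES = 16
#: At-rest symmetric key: exactly 256 bits.
STORAGE_KEY_BYTES = 32

_MAC_BYTES = 32


class EnvelopeError(ValueError):
    """Malformed envelope or key material."""


class IntegrityError(EnvelopeError):
    """Authentication tag or payload digest did not verify."""


def _derive_subkeys(key: bytes) -> tuple[bytes, bytes]:
    if len(key) != TRANSPORT_KEY_BYTES:
        raise EnvelopeError(
            f"transport key must be {TRANSPORT_KEY_BYTES} bytes, got {len(key)}"
        )
    enc = hmac.new(key, b"asthmawatch/transport-enc", hashlib.sha256).digest()[:16]
    mac = hmac.new(key, b"asthmawatch/transport-mac", hashlib.sha256).digest()
    return enc, mac


@dataclass(frozen=True)
class Envelope:
    """One sealed record payload.

    ``ciphertext`` carries the CTR ciphertext with the 32-byte HMAC tag
    appended; ``wrapped_key`` is the OAEP-wrapped 128-bit envelope key;
    ``payload_digest`` is SHA-256 of the plaintext.
    """

    key_id: str
    iv: bytes
    wrapped_key: bytes
    ciphertext: bytes
    payload_digest: bytes

    def to_json(self) -> str:
        b64 = lambda b: base64.b64encode(b).decode("ascii")
        return json.dumps(
            {
                "key_id": self.key_id,
                "iv": b64(self.iv),
                "wrapped_key": b64(self.wrapped_key),
                "ciphertext": b64(self.ciphertext),
                "digest": b64(self.payload_digest),
            }
        )

    @staticmethod
    def from_json(text: str) -> "Envelope":
        try:
            obj = json.loads(text)
            return Envelope(
                key_id=obj["key_id"],
                iv=base64.b64decode(obj["iv"]),
                wrapped_key=base64.b64decode(obj["wrapped_key"]),
                ciphertext=base64.b64decode(obj["ciphertext"]),
                payload_digest=base64.b64decode(obj["digest"]),
            )
        except (KeyError, ValueError, TypeError) as exc:
            raise EnvelopeError(f"malformed envelope JSON: {exc}") from exc


class KeyRegistry:
    """In-memory RSA keypair registry keyed by opaque key_id strings."""

    def __init__(self) -> None:
        self._keys: dict[str, RSAPrivateKey] = {}

    def generate(self, bits: int = 2048, key_id: str | None = None, rng=None) -> str:
        if key_id is None:
            key_id = secrets.token_hex(8)
        if key_id in self._keys:
            raise EnvelopeError(f"key_id {key_id!r} already registered")
        self._keys[key_id] = generate_keypair(bits=bits, rng=rng)
        return key_id

    def public(self, key_id: str) -> RSAPublicKey:
        return self._private(key_id).public_key

    def private(self, key_id: str) -> RSAPrivateKey:
        return self._private(key_id)

    def _private(self, key_id: str) -> RSAPrivateKey:
        try:
            return self._keys[key_id]
        except KeyError:
            raise EnvelopeError(f"unknown key_id {key_id!r}") from None


def seal(plaintext: bytes, recipient_public_key: RSAPublicKey, key_id: str = "") -> Envelope:
    """Seal a payload for a recipient: fresh 128-bit key per envelope."""
    if not isinstance(plaintext, (bytes, bytearray)) or len(plaintext) == 0:
        raise EnvelopeError("plaintext must be non-empty bytes")
    if not isinstance(recipient_public_key, RSAPublicKey):
        raise EnvelopeError("recipient public key must be an RSAPublicKey")
    plaintext = bytes(plaintext)
    key = secrets.token_bytes(TRANSPORT_KEY_BYTES)
    iv = secrets.token_bytes(16)
    enc_key, mac_key = _derive_subkeys(key)
    ct = AES(enc_key).ctr_xor(iv, plaintext)
    tag = hmac.new(mac_key, iv + ct, hashlib.sha256).digest()
    return Envelope(
        key_id=key_id,
        iv=iv,
        wrapped_key=oaep_encrypt(recipient_public_key, key),
        ciphertext=ct + tag,
        payload_digest=hashlib.sha256(plaintext).digest(),
    )


def open_envelope(envelope: Envelope, recipient_private_key: RSAPrivateKey) -> bytes:
    """Unwrap and decrypt an envelope, verifying tag and digest.

    Raises :class:`DecryptionError` for a mismatched key pair and
    :class:`IntegrityError` for any tampering.
    """
    if len(envelope.ciphertext) < _MAC_BYTES or len(envelope.iv) != 16:
        raise EnvelopeError("malformed envelope")
    key = oaep_decrypt(recipient_private_key, envelope.wrapped_key)
    if len(key) != TRANSPORT_KEY_BYTES:
        raise EnvelopeError("wrapped key has wrong length")
    enc_key, mac_key = _derive_subkeys(key)
    ct, tag = envelope.ciphertext[:-_MAC_BYTES], envelope.ciphertext[-_MAC_BYTES:]
    expect = hmac.new(mac_key, envelope.iv + ct, hashlib.sha256).digest()
    if not hmac.compare_digest(tag, expect):
        raise IntegrityError("envelope authentication tag mismatch")
    plaintext = AES(enc_key).ctr_xor(envelope.iv, ct)
    if hashlib.sha256(plaintext).digest() != envelope.payload_digest:
        raise IntegrityError("payload digest mismatch")
    return plaintext


def reencrypt_at_rest(plaintext: bytes, storage_key: bytes) -> bytes:
    """Encrypt a payload for storage: AES-256-CBC, digest sealed inside.

    Returns ``iv || ciphertext``; each call uses a fresh IV.
    """
    if len(storage_key) != STORAGE_KEY_BYTES:
        raise EnvelopeError(
            f"storage key must be {STORAGE_KEY_BYTES} bytes, got {len(storage_key)}"
        )
    plaintext = bytes(plaintext)
    iv = secrets.token_bytes(16)
    body = hashlib.sha256(plaintext).digest() + plaintext
    return iv + AES(storage_key).cbc_encrypt(iv, pkcs7_pad(body))


def decrypt_at_rest(blob: bytes, storage_key: bytes) -> bytes:
    """Decrypt a stored blob, verifying the embedded digest."""
    if len(storage_key) != STORAGE_KEY_BYTES:
        raise EnvelopeError(
            f"storage key must be {STORAGE_KEY_BYTES} bytes, got {len(storage_key)}"
        )
    if len(blob) < 16 + 16:
        raise EnvelopeError("stored blob too short")
    iv, ct = blob[:16], blob[16:]
    try:
        body = pkcs7_unpad(AES(storage_key).cbc_decrypt(iv, ct))
    except ValueError as exc:
        raise IntegrityError(f"stored blob failed to decrypt: {exc}") from exc
    digest, plaintext = body[:32], body[32:]
    if hashlib.sha256(plaintext).digest() != digest:
        raise IntegrityError("stored blob digest mismatch")
    return plaintext
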