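# External model files

Place the freely distributed consensus yeast SBML files here to enable
the external-data acceptance tests and the full acceptance report:

- `yeast_5.xml` — Yeast 5 model (SBML)
- `yeast_6.xml` — Yeast 6 model (SBML, fbc dialect)

Both are available from http://yeast.sf.net/. Nothing in this
repository downloads them automatically.
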