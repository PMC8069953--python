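activator
activator, inducer
adduct
agonist
agonist, activator
agonist, allosteric modulator
agonist, inducer
agonist, positive modulator
agonist, potentiator
agonist, stimulator
binder, activator
inducer
inducer, substrate
ligand, inducer
modulator, activator
modulator, inducer
modulator, ligand
positive modulator
potentiator
potentiator, activator
potentiator, binder
stimulator
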