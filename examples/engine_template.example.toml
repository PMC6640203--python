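# Worked single-point template for a Gaussian-style engine (documentation
# only; any engine reachable as `command deck -> log` works the same way).
deck_template = """%NProcShared=2
%Mem=8GB
#P B3LYP/6-311+G* SP

{TITLE}

{CHARGE} {MULT}
{COORDS}

"""
command = "g09 {deck} {log}"
energy_pattern = 'SCF Done:\s+E\(\S+\)\s+=\s+(-?\d+\.\d+)'
charge = 0
multiplicity = 1
timeout = 3600.0
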