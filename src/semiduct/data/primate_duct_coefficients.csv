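species,duct,m,c,k,g,eps
Homo sapiens,anterior,155.7,31.2,11.1,92.7,268.4
Homo sapiens,posterior,176.6,32.9,12.6,101.3,293.0
Homo sapiens,lateral,181.1,45.1,11.5,82.1,264.6
Homo sapiens,cc,6.9,0.3,,,
Homo sapiens,uc,2.6,0.1,,,
Macaca mulatta,anterior,237.5,104.1,15.5,48.6,447.7
Macaca mulatta,posterior,278.2,125.1,16.8,49.9,469.9
Macaca mulatta,lateral,260.4,118.0,21.9,46.3,541.7
Macaca mulatta,cc,13.5,1.5,,,
Macaca mulatta,uc,3.0,0.1,,,
Saimiri sciureus,anterior,296.2,180.7,23.1,32.1,722.2
Saimiri sciureus,posterior,257.6,136.4,36.0,25.6,862.6
Saimiri sciureus,lateral,297.5,187.9,33.7,27.4,908.4
Saimiri sciureus,cc,23.0,4.7,,,
Saimiri sciureus,uc,3.6,0.3,,,
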