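name,common_name,spawn_type,n_larvae_reference,spawn_days,spawn_hours,moon_phase,depth_min,depth_max,depth_profile,pld_min,pld_max,habitat,egg_phase
Cellana spp.,Opihi (limpet),broadcast,861300,1-60;121-181,,new,0,5,,3,18,intertidal,0
Pocillopora meandrina,Koa (cauliflower coral),broadcast,1671840,91-151,07:15-08:00,full,0,5,,5,90,reef,0
Octopus cyanea,Hee (octopus),benthic,1392096,1-360,,,50,100,,21,21,reef;rubble,0
Polydactylus sexfilis,Moi (Pacific threadfin),broadcast,1004640,152-243,,,50,100,,25,25,sand,1
Chlorurus perspicillatus,Uhu uliuli (spectacled parrotfish),broadcast,1404792,152-212,,,0,120,parrotfish,30,30,reef,1
Scarus rubroviolaceus,Uhu palukaluka (redlip parrotfish),broadcast,1404792,152-212,,,0,120,parrotfish,30,30,rock;reef,1
Parupeneus porphyreus,Kumu (whitesaddle goatfish),broadcast,1071252,32-90,,,0,50,goatfish,41,56,sand;rock;reef,1
Ctenochaetus strigosus,Kole (spotted surgeonfish),broadcast,1177200,60-120,,,50,100,,50,50,rock;reef;rubble,1
Caranx melampygus,Omilu (bluefin trevally),broadcast,1310616,121-243,,,0,80,caranx,140,140,sand;reef,1
Caranx ignoblis,Ulua (giant trevally),broadcast,1151040,152-243,,full,0,80,caranx,140,140,sand;rock;reef,1
Panulirus spp.,Ula (spiny lobster),benthic,1573248,152-243,,,50,100,,270,270,rock;pavement,0
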