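finger,joint,dof,muscle,mean_ma_mm,vaf_pct,rms_mm,error_pct
2,MCP,flexion,FDP,11.4,98.9,0.1,1.0
2,MCP,flexion,FDS,12.4,99.2,0.1,0.7
2,MCP,flexion,EDC,-7.4,91.2,0.7,7.7
2,MCP,flexion,LU,3.8,73.0,1.0,19.8
2,MCP,flexion,RI,5.5,57.4,2.4,42.0
2,MCP,flexion,UI,1.9,86.1,0.3,28.6
2,MCP,abduction,FDP,1.3,5.3,1.7,59.5
2,MCP,abduction,FDS,0.7,12.7,0.9,53.2
2,MCP,abduction,EDC,-1.0,89.9,0.1,8.6
2,MCP,abduction,LU,6.5,66.5,2.2,50.4
2,MCP,abduction,RI,5.6,76.6,1.3,31.7
2,MCP,abduction,UI,-6.7,88.9,0.7,9.3
2,PIP,flexion,FDP,8.5,97.7,0.2,0.5
2,PIP,flexion,FDS,7.4,89.5,0.8,9.8
2,PIP,flexion,ES,-3.6,44.5,2.0,32.8
2,PIP,flexion,RB,-2.6,33.5,2.2,14.3
2,PIP,flexion,UB,0.6,71.8,0.3,10.8
2,DIP,flexion,FDP,5.0,88.9,0.6,10.7
2,DIP,flexion,TE,-3.1,58.2,1.3,37.4
3,MCP,flexion,FDP,11.8,83.6,2.0,10.8
3,MCP,flexion,FDS,15.7,88.7,1.8,6.9
3,MCP,flexion,EDC,-6.7,65.3,2.4,23.1
3,MCP,flexion,LU,4.0,75.3,1.0,23.0
3,MCP,flexion,RI,8.0,81.5,1.5,24.7
3,MCP,flexion,UI,2.2,88.0,0.3,6.2
3,MCP,abduction,FDP,-0.1,8.9,2.6,84.8
3,MCP,abduction,FDS,0.3,4.9,2.0,36.7
3,MCP,abduction,EDC,0.4,29.8,0.6,51.6
3,MCP,abduction,LU,3.9,61.6,1.5,54.2
3,MCP,abduction,RI,8.1,63.2,3.0,56.4
3,MCP,abduction,UI,-3.8,28.8,2.7,69.4
3,PIP,flexion,FDP,7.9,94.5,0.4,3.2
3,PIP,flexion,FDS,6.5,98.8,0.1,0.7
3,PIP,flexion,ES,-4.2,42.6,2.4,52.5
3,PIP,flexion,RB,-1.1,87.3,0.1,1.1
3,PIP,flexion,UB,-0.2,86.0,0.3,67.3
3,DIP,flexion,FDP,5.2,90.6,0.5,9.7
3,DIP,flexion,TE,-2.8,72.2,0.8,22.6
4,MCP,flexion,FDP,9.1,83.0,1.6,9.6
4,MCP,flexion,FDS,9.7,87.2,1.3,11.3
4,MCP,flexion,EDC,-5.8,93.3,0.4,1.1
4,MCP,flexion,LU,3.0,75.3,0.7,1.9
4,MCP,flexion,RI,5.4,91.5,0.5,3.8
4,MCP,flexion,UI,1.7,89.1,0.2,2.9
4,MCP,abduction,FDP,-2.1,30.0,1.6,38.8
4,MCP,abduction,FDS,0.1,84.1,1.6,75.1
4,MCP,abduction,EDC,3.2,27.3,2.4,71.8
4,MCP,abduction,LU,4.0,1.6,4.0,96.8
4,MCP,abduction,RI,2.8,65.6,1.0,5.1
4,MCP,abduction,UI,-3.8,53.4,1.8,60.2
4,PIP,flexion,FDP,6.2,95.5,0.3,2.0
4,PIP,flexion,FDS,5.0,95.0,0.3,4.6
4,PIP,flexion,ES,-2.9,93.4,1.4,48.2
4,PIP,flexion,RB,-0.4,84.1,0.1,16.3
4,PIP,flexion,UB,-0.7,93.2,0.0,6.2
4,DIP,flexion,FDP,3.3,96.4,0.1,3.5
4,DIP,flexion,TE,-1.7,77.8,0.4,3.0
5,MCP,flexion,FDP,8.8,87.8,1.1,8.9
5,MCP,flexion,FDS,10.4,96.7,0.3,0.1
5,MCP,flexion,EDC,-2.2,78.2,0.6,13.1
5,MCP,flexion,LU,3.4,70.5,1.0,14.1
5,MCP,flexion,RI,6.2,81.8,1.2,11.7
5,MCP,flexion,UI,1.7,89.6,0.2,1.3
5,MCP,abduction,FDP,-2.2,99.2,2.3,31.5
5,MCP,abduction,FDS,2.2,96.7,5.3,91.5
5,MCP,abduction,EDC,2.9,73.5,1.6,74.9
5,MCP,abduction,LU,2.4,69.3,0.8,29.1
5,MCP,abduction,RI,4.1,77.5,0.9,4.3
5,MCP,abduction,UI,-6.1,54.7,2.8,57.6
5,PIP,flexion,FDP,8.0,86.7,1.1,9.8
5,PIP,flexion,FDS,7.2,97.7,0.2,1.7
5,PIP,flexion,ES,-3.0,42.8,1.9,76.1
5,PIP,flexion,RB,-0.4,33.7,0.6,34.5
5,PIP,flexion,UB,-0.8,52.1,0.6,86.6
5,DIP,flexion,FDP,5.5,99.1,0.1,0.8
5,DIP,flexion,TE,-2.0,80.1,0.4,24.7
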